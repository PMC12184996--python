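# Methods

## Input model and cleaning

The universal input is a per-frame table of seven facial landmarks (two
ears, upper/lower eyelid per eye, nose), each as `(x, y, likelihood)` in
image coordinates (origin top-left, y down, pixels). Both supported
dialects — the 3-header-row CSV (scorer / bodyparts / coords) and the
equivalent single-table HDF5 — carry no frame rate, so `fps` is supplied
out of band (config/CLI, default 30; the supported capture range is
30–60 fps). A configurable alias map lets tables from differently labelled
tracking networks load unchanged.

Trackers emit a confidence per point. Points below the likelihood
threshold (default 0.6, the conventional p-cutoff) are repaired by linear
interpolation per coordinate when the low-confidence run is interior and
at most `max_gap_frames` (default 10) long; longer or edge runs are
flagged missing (NaN). Confident points are never altered, which makes
cleaning idempotent. Linear interpolation is the simplest defensible gap
fill; it is an explicit package decision — trackers specify no downstream
handling for low-confidence output — and both parameters are exposed.

## Window heuristics

All quantities are computed on 2-second windows (tumbling in batch,
trailing per-frame in live mode).

**Eye aperture and squinting.** Aperture is the Euclidean distance between
the upper and lower eyelid (with the square root, i.e. the standard
metric). A per-second smoothed series (centred moving average over
`round(fps)` frames, window at index i covering `[i−w//2, i+(w−1)//2]`) is
provided for display; detection runs on the raw series so epoch durations
are not blurred. A frame counts as closed when aperture falls below
`closure_fraction` (default 0.4) of the open-eye baseline; the baseline is
the 75th percentile of the session's aperture series, which is robust to
the closures being detected as long as eyes are closed less than 75 % of
the time. Maximal closed runs shorter than 1 s are blinks (rewards and
grooming cause sub-second closures) and never contribute to stress; runs
of 1 s or longer are squints. A run of exactly 1 s classifies as squint.

**Motion.** For the nose (and each ear) within a window: maximum range of
motion = the diameter of the point set (max pairwise distance) — chosen
over displacement-from-first-frame so the value does not depend on window
phase, and upper-bounded by the travel distance; travel distance = the
cumulative distance between consecutive non-missing positions (gaps
bridged by one segment). The activity index is the arithmetic mean of the
two after dividing by the body scale — the simplest monotone dimensionless
combination, exposed in config. The body scale is the session median
inter-ear distance, the only stable large baseline among the seven
landmarks; it makes every score invariant under uniform rescaling and
translation of the coordinates (property-tested to 1e-9).

**Freezing** is flagged when the nose and both ear activity indices all
fall below `freeze_activity_threshold` (default 0.12, between the tracker
jitter floor of a motionless face, ≈ 0.06–0.09 with the default simulator
noise, and the quietest relaxed ears, ≈ 0.13).

**Ear asymmetry** is `|AI_L − AI_R| / (AI_L + AI_R)`, defined as 0 when
both activities are 0 (two still ears are symmetric). An **ear fold** is
declared when an ear is simultaneously immobile (range below 2 % of body
scale) and displaced (window-mean position more than 10 % of body scale
from its session-median position); immobility alone is freezing, not a
fold.

Windows are non-overlapping in batch mode; a trailing partial window is
kept when at least half full, with `valid_fraction` (non-missing frames
over the *full* window length) recording both partiality and dropouts.

## Scoring and calibration

Feature scores are monotone piecewise-linear maps, clamped to [0, 10]
(constant extrapolation beyond end knots):

- **Eyes**: 10 · min(squint-coverage ⁄ 0.6, 1) plus an aperture term
  falling from 4 (aperture ≈ 0) to 0 at 40 % of baseline. A window fully
  inside a squint scores 10; a fully open eye scores 0.
- **Nose**: inverted activity, 10 below AI = 0.12, falling to 0 at 0.4
  (relaxed nose activity sits around 0.33–0.55).
- **Ears**: inverted activity via knots (0, 10), (0.1, 9), (0.13, 2.5),
  (0.22, 0), placed between the frozen band (≈ 0.06–0.09) and the relaxed
  band (≈ 0.13–0.21); plus +4 when folded and +3 × asymmetry.

The defaults were placed so that a textbook relaxed simulation scores
below 2 and a textbook fully-stressed one above 8 (measured: ≈ 0.57 and
≈ 8.3 session means over 50 seeds each); every knot is overridable in the
YAML config. The window total is the weighted mean over features with a
positive weight and a non-missing score — missing features renormalise
rather than impute, so a missing feature behaves exactly like weight 0.
The session mean weights window totals by `valid_fraction`. Status cuts
default to an even tercile split (10⁄3, 20⁄3) of the 0–10 scale, with the
boundary values belonging to the higher band; the literature names the
three bands but no cut points, so these are package defaults. The 0–10
scale is used everywhere (some sources quote 1–10 for human raters; the
aggregation is unaffected).

Weights are applied once, in the aggregation step (not inside feature
scores): this makes weight-zero ablation algebraically exact. The ablation
analysis zeroes every subset of up to 4 features and reports the mean
absolute per-window deviation from the five-feature baseline, grouped by
subset size.

## Live mode

The monitor holds exactly one trailing window of frames plus 60 s of
rolling scalar context: per-eye aperture history for a rolling
75th-percentile baseline (config fallback before any history exists),
inter-ear distances for the body scale, and ear positions for the fold
reference. Low-confidence points are masked to missing without
interpolation — gap filling needs future frames a stream does not have.
Out-of-order frames are dropped (counted), index gaps become missing
frames. Emission is a pure function of buffer + config, so replaying a
message log is bit-reproducible, and the final emission equals the batch
trailing-window score on the same frames (`score_trailing_window`, tested
to 1e-9). Displayed status changes only after 15 consecutive identical raw
statuses (anti-flicker hysteresis); the update cadence is once per frame.
Squint epochs are detected within the trailing window, so an epoch
truncated by the window start can classify as a blink until enough closed
frames accumulate — a deliberate latency/accuracy trade-off of live mode.

## Simulator

The generator emulates tracker output, not pixels: reflecting-bounds
random walks for nose (step SD 2 px/frame relaxed, 0 frozen) and ears
(0.8 px/frame), eyelid pairs 20 px apart at rest, Poisson-timed blinks
(10/min, 0.2–0.5 s, aperture → 10 %), squints of 1.5–5 s separated by
2–4 s open gaps (aperture → 20 %), a left ear pinned 60 px away during
fold spans, isotropic Gaussian jitter (SD 0.2 px) on every point, and
2 % Bernoulli dropouts (low likelihood + large position error). Geometry
approximates a 1080p front-camera framing with a 200 px inter-ear
distance; all assertions elsewhere are scale-invariant, so the absolute
geometry is cosmetic. The 2–4 s squint gaps guarantee closed-eye coverage
below 75 % in any schedule, keeping the percentile baseline an open-eye
reference by construction. Blink/squint durations respect the 1 s
classification boundary by construction, which is what makes
detector-vs-truth recall/precision well defined.

What the simulator does **not** model: pupil dynamics, gradual aperture
transitions, correlated (non-isotropic) tracker error, lighting-dependent
likelihood drift, whisker/cheek motion, habituation within a session, and
3-D nose motion (a front camera sees X/Y only). Passing recovery tests
therefore demonstrates that the pipeline's logic is correct under the
stated noise model — not that the default calibration transfers to any
particular rig; the calibration knots and thresholds are config for
exactly that reason.

## Validation statistics

Profiles (one scalar per mouse per method) are min–max normalised onto a
common range — an affine map, so Pearson correlations are unchanged.
Pearson r/p use the standard t transform. Cohen's kappa is computed
pairwise with unweighted, linear (default for ordinal 1–10 ratings) or
quadratic disagreement weights over the sorted union of observed
categories; with more than two raters the value is the mean of all
pairwise kappas (the statistic itself is defined for two raters). The
Monte Carlo ID shuffle permutes the test profile's mouse assignment
`n_sim` times (default 10,000) and reports
`p = (1 + #{null r ≥ observed r}) / (n_sim + 1)` — the add-one estimator,
which never returns 0 and is uniform under the null (KS-tested). The
similarity statistic is Pearson r; the function is written so another
statistic can be swapped in.

## Problem sizes

Recovery and separation checks use 50 relaxed + 50 stressed sessions of
30 s at 30 fps; ablation trends use 20 sessions of 20 s across a stress
gradient; Monte Carlo calibration uses 200 repetitions of 499 draws and a
5040-permutation exhaustive oracle at n = 7. These sizes give stable
statistics (binomial SE on the ranking accuracy < 0.01) while keeping the
full suite around ten seconds.

## Numerical notes

- Distances are true Euclidean (with the square root); NaN coordinates
  propagate to NaN distances and are skipped by NaN-aware reductions.
- CSV output is written at full float precision and read back with
  round-trip float parsing, so file roundtrips are value-exact.
- Percentiles use linear interpolation (numpy default).
- A closure run at exactly the blink limit (1.0 s) is a squint; a total at
  exactly a status cut belongs to the higher band; asymmetry with two
  zero-activity ears is 0.
- Reports are byte-identical across runs for identical input and config;
  every random component (simulator, Monte Carlo) is seeded.
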