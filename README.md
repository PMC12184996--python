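# stressface

Automated stress scoring for head-fixed mice from tracked facial landmarks.

Head fixation is ubiquitous in rodent neuroscience (two-photon imaging,
in-vivo patch clamp), but an immobilised mouse cannot be assessed by posture
or locomotion, and the gold-standard hormone assays are invasive or hours
delayed. The face still tells the story: sustained eyelid closure
(squinting), freezing of the nose and ears, left/right ear asymmetry and a
folded-back ear are all established grimace-scale correlates of distress.
`stressface` consumes per-frame landmark trajectories from any markerless
tracker (the common 3-header-row CSV / HDF5 export with an
`x, y, likelihood` triplet per bodypart) and turns them into an
interpretable stress level on a 0–10 scale, in batch or live.

## The model

Seven landmarks — two ears, four eyelids, one nose — collapse into five
scored features: EAR_LEFT, EAR_RIGHT, EYE_LEFT, EYE_RIGHT, NOSE. On each
2-second window:

- **Eye aperture** `d = √((x₂−x₁)² + (y₂−y₁)²)` between upper and lower
  eyelid. Maximal runs below 40 % of the open-eye baseline (75th percentile
  of the session aperture) are closure epochs; epochs shorter than 1 s are
  blinks and are discarded, the rest are squints and drive the eye score.
- **Nose/ear activity**: the maximum range of motion (diameter of the
  window's point set) and the travel distance (cumulative path length)
  combine into an activity index
  `AI = (range/s + travel/s) / 2`, where `s` is the body scale (median
  inter-ear distance) — so every metric is camera-distance invariant.
  Low activity across nose and both ears flags **freezing**.
- **Ear asymmetry** `|AI_L − AI_R| / (AI_L + AI_R)` and an **ear fold**
  flag (immobile *and* displaced from the session-median position).

Each feature's metrics map through monotone piecewise-linear calibration
onto [0, 10]; the window total is the weighted mean
`S = Σ wᵢ sᵢ / Σ wᵢ` with user weights `wᵢ ≥ 0` (default 1; weight 0
excludes a landmark obscured by the head post, exactly equivalent to
deleting it). Totals map onto a 3-level status: okay (< 10⁄3),
caution, stressed (≥ 20⁄3).

The package also ships a session simulator with frame-accurate ground
truth (the basis of all recovery tests), the cross-method validation
statistics (min–max profile normalisation, Pearson r, pairwise Cohen's
kappa, Monte Carlo mouse-ID shuffle), and a live monitor that scores a
trailing window per streamed frame.

## Worked example

```python
from stressface import AppConfig, clean_trajectories, score_session
from stressface.session_simulator import SimulationConfig, simulate_session

config = AppConfig()
sim = simulate_session(SimulationConfig(
    seed=42, duration_s=30.0,
    state_schedule=[("relaxed", 15.0), ("stressed_combined", 15.0)],
))
table = clean_trajectories(sim.table, config.cleaning)
report = score_session(table, config=config)
print(f"{report.session_mean:.2f}/10 -> {report.session_status}")
```

prints `4.30/10 -> caution`: the relaxed half scores windows near 0
("okay"), the stressed half (squints + freezing + folded ear) scores
windows above 9 ("stressed"), and the session mean lands in between. See
`examples/` for narrative scripts covering scoring, ablation, live replay
and the validation statistics, or use the CLI:

```bash
stressface simulate --out traj.csv --seed 7 --duration-s 30
stressface score --input traj.csv --fps 30 --out report.json
stressface ablate --input traj.csv
stressface live --replay traj.csv --fps 30
stressface validate --scores mc.csv --raters raters.csv --fcm fcm.csv
```

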