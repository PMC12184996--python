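"""Method-comparison statistics across per-mouse stress profiles.

A profile is one scalar per mouse from one measurement method: the
automated score (0-10), the mean of human rater scores (1-10), or fecal
corticosterone metabolites (FCM, ng per 50 mg of feces).  Profiles are
min-max normalised onto a common range, compared with Pearson correlation
and (for ordinal rater matrices) Cohen's kappa, and the chance level of a
profile similarity is estimated with a Monte Carlo mouse-ID shuffle.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy import stats as sps


@dataclass(frozen=True)
class MethodProfile:
    """Per-mouse scalar values from one stress-evaluation method."""

    mouse_ids: tuple[str, ...]
    values: tuple[float, ...]
    method: str = ""  # e.g. "automated", "raters", "fcm"

    def __post_init__(self) -> None:
        ids = tuple(str(i) for i in self.mouse_ids)
        vals = tuple(float(v) for v in self.values)
        if len(ids) != len(vals):
            raise ValueError("mouse_ids and values must have equal length")
        if len(set(ids)) != len(ids):
            raise ValueError("mouse ids must be unique")
        if not all(np.isfinite(vals)):
            raise ValueError("profile values must be finite")
        object.__setattr__(self, "mouse_ids", ids)
        object.__setattr__(self, "values", vals)

    def __len__(self) -> int:
        return len(self.values)

    def array(self) -> np.ndarray:
        return np.asarray(self.values, dtype=float)


def _aligned(a: MethodProfile, b: MethodProfile) -> tuple[np.ndarray, np.ndarray]:
    if a.mouse_ids != b.mouse_ids:
        raise ValueError("profiles are not aligned on the same mouse ids")
    return a.array(), b.array()


def normalize_profile(
    p: MethodProfile, target_range: tuple[float, float] = (0.0, 10.0)
) -> MethodProfile:
    """Min-max rescale onto [lo, hi]; order-preserving and affine, so it
    leaves Pearson correlations with other profiles unchanged."""
    lo, hi = target_range
    if hi <= lo:
        raise ValueError("target range must satisfy lo < hi")
    v = p.array()
    vmin, vmax = v.min(), v.max()
    if vmax == vmin:
        raise ValueError("cannot normalize a constant profile")
    scaled = lo + (v - vmin) * (hi - lo) / (vmax - vmin)
    return replace(p, values=tuple(scaled))


def pearson(a: MethodProfile, b: MethodProfile) -> tuple[float, float]:
    """Sample Pearson r and its two-sided p-value (t transform)."""
    va, vb = _aligned(a, b)
    if len(va) < 3:
        raise ValueError("need at least 3 aligned mice")
    if va.std() == 0 or vb.std() == 0:
        raise ValueError("zero-variance profile")
    r, p = sps.pearsonr(va, vb)
    return float(r), float(p)


def _pair_kappa(a: np.ndarray, b: np.ndarray, weighting: str) -> float:
    cats = np.unique(np.concatenate([a, b]))
    k = len(cats)
    if k == 1:
        if np.array_equal(a, b):
            return 1.0
        raise ValueError("single rating category with imperfect agreement")
    index = {c: i for i, c in enumerate(cats)}
    ia = np.array([index[x] for x in a])
    ib = np.array([index[x] for x in b])
    observed = np.zeros((k, k))
    for i, j in zip(ia, ib):
        observed[i, j] += 1
    observed /= observed.sum()
    pa = observed.sum(axis=1)
    pb = observed.sum(axis=0)
    expected = np.outer(pa, pb)
    ii, jj = np.meshgrid(np.arange(k), np.arange(k), indexing="ij")
    if weighting == "unweighted":
        w = (ii != jj).astype(float)
    elif weighting == "linear":
        w = np.abs(ii - jj) / (k - 1)
    elif weighting == "quadratic":
        w = ((ii - jj) / (k - 1)) ** 2
    else:
        raise ValueError(f"unknown weighting {weighting!r}")
    de = float((w * expected).sum())
    if de == 0:
        return 1.0
    return 1.0 - float((w * observed).sum()) / de


def cohens_kappa(ratings: Sequence[Sequence[float]], weighting: str = "linear") -> float:
    """Inter-rater agreement, chance-corrected: kappa = (po - pe)/(1 - pe).

    ``ratings`` is a raters x items matrix of ordinal scores.  With more
    than two raters the value is the mean of all pairwise kappas (the
    statistic itself is strictly pairwise).  Weighting discounts
    near-misses on the ordinal scale: "unweighted", "linear" (default for
    1-10 ratings) or "quadratic".
    """
    mat = np.asarray(ratings, dtype=float)
    if mat.ndim != 2 or mat.shape[0] < 2:
        raise ValueError("need a raters x items matrix with >= 2 raters")
    pairs = [
        _pair_kappa(mat[i], mat[j], weighting)
        for i in range(len(mat))
        for j in range(i + 1, len(mat))
    ]
    return float(np.mean(pairs))


def _pearson_many(perms: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """Pearson r of each row of `perms` against `ref` (vectorised)."""
    pc = perms - perms.mean(axis=1, keepdims=True)
    rc = ref - ref.mean()
    denom = np.sqrt((pc**2).sum(axis=1) * (rc**2).sum())
    return (pc @ rc) / denom


def monte_carlo_id_shuffle(
    test: MethodProfile,
    reference: MethodProfile,
    n_sim: int = 10_000,
    seed: int | None = None,
) -> tuple[float, float]:
    """Chance level of the observed profile similarity under ID shuffling.

    The similarity statistic is Pearson r.  The null is generated by
    ``n_sim`` uniformly random permutations of the test profile's
    mouse-ID assignment; the p-value uses the add-one estimator
    ``(1 + #{null r >= observed r}) / (n_sim + 1)`` so it can never be 0.
    """
    if n_sim < 1:
        raise ValueError("n_sim must be >= 1")
    vt, vr = _aligned(test, reference)
    if len(vt) < 3:
        raise ValueError("need at least 3 aligned mice")
    observed, _ = pearson(test, reference)
    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(vt) for _ in range(n_sim)])
    null_r = _pearson_many(perms, vr)
    p = (1 + int(np.sum(null_r >= observed - 1e-12))) / (n_sim + 1)
    return observed, float(p)
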