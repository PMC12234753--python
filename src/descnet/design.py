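"""Study-design computations: correlation power analysis, Spearman-Brown
reliability forecasting, maximum-variation stimulus sampling, and the
subset-sufficiency curve for the stimulus set."""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Optional, Sequence

import numpy as np
from scipy import stats

from .textprep import DocumentTermMatrix


def correlation_power_n(r: float, alpha: float = 0.05, power: float = 0.95) -> int:
    """Sample size to detect a correlation r via the Fisher-z approximation:
    n = ceil( ((z_{1-alpha/2} + z_power) / atanh r)^2 + 3 )."""
    if not (0 < r < 1):
        raise ValueError("r must be in (0, 1)")
    if not (0 < alpha < 1 and 0 < power < 1):
        raise ValueError("alpha and power must be in (0, 1)")
    za = stats.norm.ppf(1 - alpha / 2)
    zb = stats.norm.ppf(power)
    return int(math.ceil(((za + zb) / math.atanh(r)) ** 2 + 3))


def spearman_brown_alpha(rbar: float, k: int) -> float:
    """Standardized Cronbach's alpha of k parallel raters with mean
    pairwise correlation rbar: alpha = k rbar / (1 + (k-1) rbar)."""
    if not (0 < rbar < 1):
        raise ValueError("rbar must be in (0, 1)")
    if k < 1:
        raise ValueError("k must be >= 1")
    return k * rbar / (1 + (k - 1) * rbar)


def spearman_brown_k(rbar: float, alpha_target: float) -> int:
    """Raters needed to reach a target standardized alpha:
    k = ceil( alpha (1 - rbar) / (rbar (1 - alpha)) )."""
    if not (0 < rbar < 1 and 0 < alpha_target < 1):
        raise ValueError("rbar and alpha_target must be in (0, 1)")
    if alpha_target <= rbar:
        return 1
    return int(math.ceil(alpha_target * (1 - rbar) / (rbar * (1 - alpha_target))))


@dataclass
class FeatureMatrix:
    """Items x features matrix with a stratum label per item."""

    item_ids: list
    features: np.ndarray
    strata: Dict[object, object]

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        if self.features.shape[0] != len(self.item_ids):
            raise ValueError("features rows must match item_ids")
        if not np.all(np.isfinite(self.features)):
            raise ValueError("features contain missing/non-finite values")
        missing = [i for i in self.item_ids if i not in self.strata]
        if missing:
            raise ValueError(f"items without stratum label: {missing[:5]}")


def _largest_remainder(sizes: np.ndarray, total: int) -> np.ndarray:
    """Proportional integer quotas by the largest-remainder rule."""
    shares = sizes / sizes.sum() * total
    base = np.floor(shares).astype(int)
    rem = total - base.sum()
    order = np.argsort(-(shares - base))
    base[order[:rem]] += 1
    return base


def max_variation_sample(
    fm: FeatureMatrix,
    n_total: int,
    l2_normalize: bool = True,
) -> list:
    """Stratified greedy selection of maximally varied items.

    Rows are L2-normalized (so high-dimensional feature blocks do not
    dominate); per-stratum quotas are proportional with largest-remainder
    rounding.  Within a stratum the seed is the item farthest from the
    stratum centroid, then items are added greedily to maximize the mean
    per-feature variance of the selected set.
    """
    if n_total > len(fm.item_ids):
        raise ValueError("n_total exceeds item count")
    F = fm.features.copy()
    if l2_normalize:
        norms = np.linalg.norm(F, axis=1)
        if (norms == 0).any():
            bad = [fm.item_ids[i] for i in np.flatnonzero(norms == 0)[:5]]
            raise ValueError(f"zero feature rows cannot be L2-normalized: {bad}")
        F = F / norms[:, None]
    labels = [fm.strata[i] for i in fm.item_ids]
    groups = sorted(set(labels), key=str)
    sizes = np.array([labels.count(g) for g in groups])
    if (sizes == 0).any():
        raise ValueError("every stratum must be nonempty")
    quotas = _largest_remainder(sizes, n_total)
    for g, q, s in zip(groups, quotas, sizes):
        if q > s:
            raise ValueError(f"stratum {g!r} quota {q} exceeds its size {s}")
    selected: list = []
    for g, q in zip(groups, quotas):
        idx = [i for i, lab in enumerate(labels) if lab == g]
        if q == 0:
            continue
        sub = F[idx]
        centroid = sub.mean(axis=0)
        pick = [int(np.argmax(((sub - centroid) ** 2).sum(axis=1)))]
        while len(pick) < q:
            best, best_val = None, -np.inf
            chosen = sub[pick]
            for cand in range(len(idx)):
                if cand in pick:
                    continue
                trial = np.vstack([chosen, sub[cand]])
                val = trial.var(axis=0).mean()
                if val > best_val:
                    best, best_val = cand, val
            pick.append(best)
        selected.extend(fm.item_ids[idx[c]] for c in pick)
    return selected


@dataclass
class SufficiencyCurve:
    sizes: list
    mean_rho: np.ndarray
    minimal_sufficient: Optional[int]
    rho_threshold: float
    reps: int
    seed: int


def subset_sufficiency(
    dtm: DocumentTermMatrix,
    rho_threshold: float = 0.6,
    grid: Sequence[int] = (),
    reps: int = 20,
    seed: int = 0,
    normalized: bool = False,
) -> SufficiencyCurve:
    """How many videos reproduce the full-corpus covariance structure.

    Per grid size and repetition, that many video rows are sampled without
    replacement, the word covariance matrix recomputed, and the Spearman
    rho between vectorized lower triangles of the subset vs. the full
    covariance recorded.  Returns the mean curve and the smallest size
    whose mean rho exceeds the threshold.
    """
    X = dtm.values
    n = X.shape[0]
    grid = sorted(int(g) for g in grid)
    if not grid:
        raise ValueError("grid of subset sizes is required")
    if min(grid) < 3:
        raise ValueError("grid sizes must be >= 3")
    if max(grid) >= n:
        raise ValueError("grid sizes must be smaller than the number of videos")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    if normalized:
        lo, hi = X.min(axis=0), X.max(axis=0)
        span = np.where(hi > lo, hi - lo, 1.0)
        X = (X - lo) / span
    full = np.cov(X, rowvar=False)
    il = np.tril_indices(X.shape[1], -1)
    full_v = full[il]
    rng = np.random.default_rng(seed)
    means = np.empty(len(grid))
    for gi, size in enumerate(grid):
        vals = np.empty(reps)
        for r in range(reps):
            rows = rng.choice(n, size=size, replace=False)
            sub = np.cov(X[rows], rowvar=False)
            vals[r] = stats.spearmanr(sub[il], full_v).statistic
        means[gi] = vals.mean()
    ok = [s for s, m in zip(grid, means) if m > rho_threshold]
    return SufficiencyCurve(
        sizes=grid, mean_rho=means,
        minimal_sufficient=(min(ok) if ok else None),
        rho_threshold=rho_threshold, reps=reps, seed=seed,
    )
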