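"""Model comparison: SRMR, resampled SRMR distributions, Welch/Cohen
statistics, lightweight SEM fit indices, and the permutation network
comparison test between two samples.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from ._utils import nearest_psd_correlation, spearman_corr
from .network import SnmSettings, fit_snm
from .textprep import CorrelationStructure, DocumentTermMatrix


def _check_aligned(a: CorrelationStructure, b: CorrelationStructure) -> None:
    if list(a.words) != list(b.words):
        raise ValueError("correlation structures have mismatched word orderings")


def srmr(R_obs: CorrelationStructure, R_hat: CorrelationStructure) -> float:
    """Root mean squared off-diagonal residual between two correlation
    matrices (lower triangle only; diagonals are identically 1)."""
    _check_aligned(R_obs, R_hat)
    p = len(R_obs.words)
    il = np.tril_indices(p, -1)
    resid = R_obs.matrix[il] - R_hat.matrix[il]
    return float(np.sqrt(np.mean(resid**2)))


def srmr_sampling_distribution(
    R_hat: CorrelationStructure,
    R_obs: CorrelationStructure,
    n: int,
    draws: int = 100,
    seed: int = 0,
    target: str = "observed",
) -> np.ndarray:
    """Parametric SRMR sampling distribution for a model-implied matrix.

    Each draw simulates n multivariate-normal observations with covariance
    R_hat, computes the sample correlation matrix, and records its SRMR
    against the observed matrix (``target="observed"``, default) or
    against R_hat itself (``target="implied"``).
    """
    _check_aligned(R_obs, R_hat)
    if target not in ("observed", "implied"):
        raise ValueError("target must be 'observed' or 'implied'")
    M = nearest_psd_correlation(R_hat.matrix)
    p = M.shape[0]
    w, V = np.linalg.eigh(M)
    w = np.clip(w, 0.0, None)
    A = V * np.sqrt(w)  # M = A A'
    ref = R_obs if target == "observed" else R_hat
    rng = np.random.default_rng(seed)
    il = np.tril_indices(p, -1)
    out = np.empty(draws)
    for d in range(draws):
        X = rng.standard_normal((n, p)) @ A.T
        C = np.corrcoef(X, rowvar=False)
        out[d] = np.sqrt(np.mean((ref.matrix[il] - C[il]) ** 2))
    return out


@dataclass
class ComparisonReport:
    srmr_point: dict
    srmr_distribution: dict
    welch_t: float
    welch_df: float
    p_value: float
    cohens_d: float
    d_ci: Tuple[float, float]
    draws: int
    seed: int


def compare_models(dist_a: Sequence[float], dist_b: Sequence[float]):
    """Welch two-sample t (Satterthwaite df) and Cohen's d with a
    normal-approximation 95% CI, comparing two SRMR distributions."""
    a = np.asarray(dist_a, float)
    b = np.asarray(dist_b, float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both samples need length >= 2")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0 and a.mean() == b.mean():
        raise ValueError("degenerate samples: zero variance and equal means")
    res = stats.ttest_ind(a, b, equal_var=False)
    na, nb = len(a), len(b)
    sp = np.sqrt(((na - 1) * va + (nb - 1) * vb) / (na + nb - 2))
    d = float((a.mean() - b.mean()) / sp) if sp > 0 else np.inf * np.sign(a.mean() - b.mean())
    se_d = np.sqrt((na + nb) / (na * nb) + d * d / (2 * (na + nb - 2)))
    return {
        "welch_t": float(res.statistic),
        "welch_df": float(res.df),
        "p_value": float(res.pvalue),
        "cohens_d": d,
        "d_ci": (d - 1.959963984540054 * se_d, d + 1.959963984540054 * se_d),
    }


@dataclass
class FitIndices:
    chi2: float
    df: int
    rmsea: float
    rmsea_ci: Tuple[float, float]
    cfi: float
    tli: float


def _rmsea_ci(T: float, df: int, n: int, level: float = 0.90) -> Tuple[float, float]:
    """Noncentral-chi-square confidence bounds on RMSEA."""
    lo_q, hi_q = (1 + level) / 2, (1 - level) / 2  # cdf targets 0.95 / 0.05

    def bound(q):
        if stats.chi2.cdf(T, df) < q:  # nc=0 already exceeds target
            return 0.0
        f = lambda nc: stats.ncx2.cdf(T, df, nc) - q
        hi = max(T, df) + 1.0
        while f(hi) > 0:
            hi *= 2.0
            if hi > 1e8:
                break
        from scipy.optimize import brentq
        try:
            nc = brentq(f, 0.0, hi)
        except ValueError:
            return 0.0
        return float(np.sqrt(max(nc, 0.0) / (df * (n - 1))))

    return bound(lo_q), bound(hi_q)


def fit_indices(
    R_obs: CorrelationStructure,
    R_hat: CorrelationStructure,
    n: int,
    free_edges: int,
) -> FitIndices:
    """ML-discrepancy chi-square with RMSEA/CFI/TLI for a fixed implied
    matrix evaluated against the observed correlations.

    F_ML = log|R_hat| - log|R_obs| + tr(R_obs R_hat^{-1}) - p;
    T = (n-1) F_ML; df = p(p-1)/2 - free_edges.  The baseline model is the
    independence structure (identity implied matrix).
    """
    _check_aligned(R_obs, R_hat)
    p = len(R_obs.words)
    df = p * (p - 1) // 2 - int(free_edges)
    if df <= 0:
        raise ValueError("df <= 0: model is saturated or over-parameterized")
    So = nearest_psd_correlation(R_obs.matrix, eps=1e-8)
    Sh = nearest_psd_correlation(R_hat.matrix, eps=1e-8)
    sign_h, ld_h = np.linalg.slogdet(Sh)
    sign_o, ld_o = np.linalg.slogdet(So)
    if sign_h <= 0 or sign_o <= 0:
        raise np.linalg.LinAlgError("correlation matrices must be positive definite")
    F = ld_h - ld_o + float(np.trace(So @ np.linalg.inv(Sh))) - p
    F = max(F, 0.0)
    T = (n - 1) * F
    # independence baseline: implied identity
    F_b = -ld_o  # tr(So * I) = p cancels the -p term
    T_b = (n - 1) * max(F_b, 0.0)
    df_b = p * (p - 1) // 2
    rmsea = float(np.sqrt(max(T - df, 0.0) / (df * (n - 1))))
    ci = _rmsea_ci(T, df, n)
    denom = max(T_b - df_b, T - df, 0.0)
    cfi = 1.0 if denom == 0 else 1.0 - max(T - df, 0.0) / denom
    if T_b / df_b - 1.0 <= 0:
        tli = 1.0
    else:
        tli = (T_b / df_b - T / df) / (T_b / df_b - 1.0)
    return FitIndices(chi2=float(T), df=df, rmsea=rmsea, rmsea_ci=ci,
                      cfi=float(min(cfi, 1.0)), tli=float(min(tli, 1.0)))


# ---------------------------------------------------------------------------
# network comparison test
# ---------------------------------------------------------------------------

@dataclass
class NCTResult:
    shared_words: list
    observed_diff: np.ndarray
    null_max: np.ndarray
    per_edge_p: np.ndarray
    n_perm: int
    seed: int


def _counts_to_partials(X: np.ndarray, n: int, settings: SnmSettings) -> np.ndarray:
    """Counts -> minmax (constant columns kept at 0) -> Spearman -> SNM.

    Permutation resamples can make a word constant; such columns get zero
    correlations instead of being dropped so all refits share one node set.
    The nonparanormal step is rank-monotone and cannot change Spearman, so
    it is skipped inside this hot loop.
    """
    C = spearman_corr(X, on_constant="zero")
    S = CorrelationStructure(words=[str(i) for i in range(X.shape[1])], matrix=C,
                             n_effective=n)
    sol = fit_snm(S, n=n, settings=settings)
    return sol.partials


def network_comparison_test(
    dtm_a: DocumentTermMatrix,
    dtm_b: DocumentTermMatrix,
    top_m: int = 300,
    n_perm: int = 1000,
    seed: int = 0,
    snm_settings: Optional[SnmSettings] = None,
) -> NCTResult:
    """Permutation test for edge differences between two samples' networks.

    The top_m most frequently mentioned words shared by both corpora are
    selected (total mention count, ties lexicographic); each sample's SNM
    is fitted and the observed edge differences recorded.  Null networks
    are built by resampling rows with replacement from the merged
    document-term matrix (matching each sample's row count) and refitting;
    the max absolute edge difference per permutation gives a familywise-
    corrected per-edge p-value via the add-one estimator.
    """
    if dtm_a.state != "counts" or dtm_b.state != "counts":
        raise ValueError("network comparison test expects counts-state matrices")
    settings = snm_settings or SnmSettings(n_lambdas=30, patience=5)
    shared = sorted(set(dtm_a.words) & set(dtm_b.words))
    if len(shared) < top_m:
        raise ValueError(
            f"only {len(shared)} shared words; top_m={top_m} requested"
        )
    ia = {w: i for i, w in enumerate(dtm_a.words)}
    ib = {w: i for i, w in enumerate(dtm_b.words)}
    totals = {
        w: dtm_a.values[:, ia[w]].sum() + dtm_b.values[:, ib[w]].sum()
        for w in shared
    }
    chosen = sorted(shared, key=lambda w: (-totals[w], w))[:top_m]
    Xa = dtm_a.values[:, [ia[w] for w in chosen]]
    Xb = dtm_b.values[:, [ib[w] for w in chosen]]
    na, nb = Xa.shape[0], Xb.shape[0]
    Pa = _counts_to_partials(Xa, na, settings)
    Pb = _counts_to_partials(Xb, nb, settings)
    observed = Pa - Pb
    merged = np.vstack([Xa, Xb])
    rng = np.random.default_rng(seed)
    null_max = np.empty(n_perm)
    m = top_m
    iu = np.triu_indices(m, 1)
    for b in range(n_perm):
        ra = rng.integers(0, na + nb, size=na)
        rb = rng.integers(0, na + nb, size=nb)
        Qa = _counts_to_partials(merged[ra], na, settings)
        Qb = _counts_to_partials(merged[rb], nb, settings)
        null_max[b] = np.abs(Qa - Qb)[iu].max()
    absd = np.abs(observed)
    sorted_null = np.sort(null_max)
    exceed = n_perm - np.searchsorted(sorted_null, absd, side="left")
    per_edge_p = (1.0 + exceed) / (n_perm + 1.0)
    np.fill_diagonal(per_edge_p, 1.0)
    return NCTResult(
        shared_words=chosen, observed_diff=observed, null_max=null_max,
        per_edge_p=per_edge_p, n_perm=n_perm, seed=seed,
    )
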