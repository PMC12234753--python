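"""Shared numerical helpers: PSD repair, Spearman matrices, seeding."""

from __future__ import annotations

import numpy as np
from scipy import stats


def nearest_psd_correlation(S: np.ndarray, eps: float = 0.0) -> np.ndarray:
    """Project a symmetric matrix to the PSD cone and rescale to unit diagonal.

    Eigenvalues are clipped at ``eps`` (default 0) and the result is
    renormalized so the diagonal is exactly 1.  Rank-based correlation
    matrices need not be PSD, so this repair precedes any factoring or
    graphical-lasso step.
    """
    S = np.asarray(S, dtype=float)
    S = 0.5 * (S + S.T)
    w, V = np.linalg.eigh(S)
    if w.min() >= eps:
        out = S.copy()
    else:
        w = np.clip(w, eps, None)
        out = (V * w) @ V.T
    d = np.sqrt(np.diag(out))
    d[d <= 0] = 1.0
    out = out / np.outer(d, d)
    np.fill_diagonal(out, 1.0)
    return 0.5 * (out + out.T)


def spearman_corr(X: np.ndarray, on_constant: str = "error") -> np.ndarray:
    """Pairwise Spearman correlations (average-rank ties) of the columns of X.

    on_constant: "error" raises on a zero-variance column; "zero" sets the
    correlations of constant columns to 0 (used inside permutation loops
    where resampling can wipe out a word's variation).
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if n < 3:
        raise ValueError("Spearman correlation needs at least 3 rows")
    R = np.empty_like(X)
    for j in range(p):
        R[:, j] = stats.rankdata(X[:, j], method="average")
    sd = R.std(axis=0)
    const = sd == 0
    if const.any():
        if on_constant == "error":
            bad = int(np.flatnonzero(const)[0])
            raise ValueError(
                f"column {bad} has zero variance; drop constant columns before "
                "computing correlations"
            )
        R[:, const] = 0.0
    Z = R - R.mean(axis=0)
    denom = np.sqrt((Z * Z).sum(axis=0))
    denom[const] = 1.0
    C = (Z.T @ Z) / np.outer(denom, denom)
    C[const, :] = 0.0
    C[:, const] = 0.0
    np.fill_diagonal(C, 1.0)
    C = np.clip(C, -1.0, 1.0)
    return 0.5 * (C + C.T)


def child_seed(seed: int, *key: int) -> int:
    """Derive a reproducible child seed below 2**31 from a parent seed."""
    ss = np.random.SeedSequence([int(seed), *map(int, key)])
    return int(ss.generate_state(1)[0] % (2**31 - 1))


def check_symmetric(M: np.ndarray, tol: float = 1e-10, what: str = "matrix") -> np.ndarray:
    M = np.asarray(M, dtype=float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError(f"{what} must be square")
    if np.max(np.abs(M - M.T)) > tol:
        raise ValueError(f"{what} is not symmetric within {tol}")
    return 0.5 * (M + M.T)
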