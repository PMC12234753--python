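"""Exploratory factor analysis: rank selection and fitting.

Rank selection uses Owen-Perry (2,2)-fold bi-cross-validation: rows and
columns are each split in half, and every held-out block is predicted from
the complementary blocks through a rank-k truncated-SVD reconstruction
A_hat = B D_k^+ C.  Extraction is minimum-residual (minres): the
uniquenesses are optimized so the top-k eigenstructure of S - diag(psi)
reproduces the off-diagonal correlations with least squared error.
Rotation is oblique oblimin via the gradient-projection algorithm, the
de-facto default pairing in psychometric tooling.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import optimize

from ._utils import nearest_psd_correlation
from .textprep import CorrelationStructure, DocumentTermMatrix


@dataclass
class BCVReport:
    candidate_ks: list
    mean_heldout_error: np.ndarray
    chosen_k: int
    n_iterations: int
    seed: int

    def __post_init__(self) -> None:
        errs = np.asarray(self.mean_heldout_error, dtype=float)
        best = min(
            (e, k) for k, e in zip(self.candidate_ks, errs)
        )
        if best[1] != self.chosen_k:
            raise ValueError("chosen_k must attain the minimum mean error")


@dataclass
class FactorSolution:
    k: int
    loadings: np.ndarray            # p x k pattern matrix
    factor_correlations: np.ndarray  # k x k, unit diagonal
    variance_explained: dict         # per-factor proportions + total
    rotation: str = "oblimin"
    words: Optional[list] = None

    def __post_init__(self) -> None:
        Phi = np.asarray(self.factor_correlations, dtype=float)
        if np.max(np.abs(Phi - Phi.T)) > 1e-8:
            raise ValueError("factor correlation matrix must be symmetric")
        if np.max(np.abs(np.diag(Phi) - 1)) > 1e-8:
            raise ValueError("factor correlation diagonal must be 1")
        if np.linalg.eigvalsh(Phi).min() < -1e-8:
            raise ValueError("factor correlation matrix must be PSD")


def bcv_select_rank(
    dtm,
    candidate_ks: Sequence[int],
    n_iterations: int = 100,
    seed: int = 0,
) -> BCVReport:
    """Owen-Perry (2,2) bi-cross-validation over candidate ranks.

    Per iteration, rows and columns are randomly split into two folds; each
    of the four held-out blocks A is reconstructed from the complementary
    blocks as B D_k^+ C (D_k = rank-k truncation of the training block) and
    squared reconstruction error is accumulated.  Ties in the mean error
    break toward the smaller rank.
    """
    X = dtm.values if isinstance(dtm, DocumentTermMatrix) else np.asarray(dtm, float)
    n, p = X.shape
    ks = sorted(int(k) for k in candidate_ks)
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    if max(ks) >= min(n, p) / 2:
        raise ValueError(
            f"max candidate rank {max(ks)} too large for fold sizes of a "
            f"{n}x{p} matrix (need k < min(n, p)/2)"
        )
    rng = np.random.default_rng(seed)
    err = np.zeros(len(ks))
    for _ in range(n_iterations):
        rperm = rng.permutation(n)
        cperm = rng.permutation(p)
        rfolds = (rperm[: n // 2], rperm[n // 2 :])
        cfolds = (cperm[: p // 2], cperm[p // 2 :])
        for ri in range(2):
            for ci in range(2):
                I, J = rfolds[ri], cfolds[ci]
                Ic, Jc = rfolds[1 - ri], cfolds[1 - ci]
                A = X[np.ix_(I, J)]
                B = X[np.ix_(I, Jc)]
                C = X[np.ix_(Ic, J)]
                D = X[np.ix_(Ic, Jc)]
                U, s, Vt = np.linalg.svd(D, full_matrices=False)
                BV = B @ Vt.T      # |I| x r
                UC = U.T @ C       # r x |J|
                for ki, k in enumerate(ks):
                    kk = min(k, len(s))
                    with np.errstate(divide="ignore"):
                        inv_s = np.where(s[:kk] > 1e-12, 1.0 / s[:kk], 0.0)
                    A_hat = (BV[:, :kk] * inv_s) @ UC[:kk]
                    err[ki] += np.sum((A - A_hat) ** 2)
    mean_err = err / (4 * n_iterations)
    chosen = ks[int(np.argmin(mean_err))]
    return BCVReport(
        candidate_ks=ks,
        mean_heldout_error=mean_err,
        chosen_k=chosen,
        n_iterations=n_iterations,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# minres extraction
# ---------------------------------------------------------------------------

def _loadings_from_psi(S: np.ndarray, psi: np.ndarray, k: int) -> np.ndarray:
    Sr = S - np.diag(psi)
    w, V = np.linalg.eigh(Sr)
    idx = np.argsort(w)[::-1][:k]
    w_k = np.clip(w[idx], 0.0, None)
    return V[:, idx] * np.sqrt(w_k)


def _minres_objective(psi, S, k, iu):
    L = _loadings_from_psi(S, psi, k)
    R = S - L @ L.T
    return float(np.sum(R[iu] ** 2))


def _minres(S: np.ndarray, k: int, max_iter: int = 1000):
    p = S.shape[0]
    iu = np.triu_indices(p, 1)
    # start from squared multiple correlations
    try:
        Sinv = np.linalg.inv(S + 1e-8 * np.eye(p))
        smc = 1.0 - 1.0 / np.diag(Sinv)
    except np.linalg.LinAlgError:
        smc = np.full(p, 0.5)
    psi0 = np.clip(1.0 - smc, 0.01, 0.99)
    res = optimize.minimize(
        _minres_objective,
        psi0,
        args=(S, k, iu),
        method="L-BFGS-B",
        bounds=[(0.005, 1.0)] * p,
        options={"maxiter": max_iter, "ftol": 1e-12, "gtol": 1e-8},
    )
    if not res.success and res.status != 1:  # status 1 = maxiter
        raise RuntimeError(
            f"minres failed to converge: {res.message} (nit={res.nit})"
        )
    return _loadings_from_psi(S, res.x, k)


# ---------------------------------------------------------------------------
# oblimin rotation (gradient projection, oblique case)
# ---------------------------------------------------------------------------

def _oblimin_vgq(L: np.ndarray, gamma: float = 0.0):
    p, k = L.shape
    L2 = L * L
    N = np.ones((k, k)) - np.eye(k)
    if gamma != 0.0:
        C = np.eye(p) - (gamma / p) * np.ones((p, p))
        X = C @ L2 @ N
    else:
        X = L2 @ N
    return float(np.sum(L2 * X)) / 4.0, L * X


def _gpa_oblique(A: np.ndarray, T0: np.ndarray, max_iter: int = 1000, tol: float = 1e-7):
    T = T0.copy()
    al = 1.0
    Ti = np.linalg.inv(T)
    L = A @ Ti.T
    f, Gq = _oblimin_vgq(L)
    G = -(L.T @ Gq @ Ti).T
    for _ in range(max_iter):
        Gp = G - T * (T * G).sum(axis=0)
        s = np.linalg.norm(Gp)
        if s < tol:
            break
        al *= 2.0
        for _ls in range(30):
            X = T - al * Gp
            X = X / np.sqrt((X * X).sum(axis=0))
            Ti = np.linalg.inv(X)
            Lt = A @ Ti.T
            ft, Gq = _oblimin_vgq(Lt)
            if ft < f - 0.5 * s * s * al:
                break
            al /= 2.0
        T, f, L = X, ft, Lt
        G = -(L.T @ Gq @ np.linalg.inv(T)).T
    Phi = T.T @ T
    return L, Phi, f


def _rotate_oblimin(L0: np.ndarray, seed: int = 0, n_starts: int = 5):
    k = L0.shape[1]
    if k == 1:
        return L0, np.eye(1)
    rng = np.random.default_rng(seed)
    best = None
    starts = [np.eye(k)] + [
        np.linalg.qr(rng.standard_normal((k, k)))[0] for _ in range(n_starts - 1)
    ]
    for T0 in starts:
        L, Phi, f = _gpa_oblique(L0, T0)
        if best is None or f < best[2]:
            best = (L, Phi, f)
    return best[0], best[1]


def _tidy_solution(L: np.ndarray, Phi: np.ndarray):
    """Order factors by explained variance and fix signs (sum of loadings >= 0)."""
    ss = np.diag(Phi @ L.T @ L)
    order = np.argsort(ss)[::-1]
    L = L[:, order]
    Phi = Phi[np.ix_(order, order)]
    signs = np.where(L.sum(axis=0) < 0, -1.0, 1.0)
    L = L * signs
    Phi = Phi * np.outer(signs, signs)
    np.fill_diagonal(Phi, 1.0)
    return L, 0.5 * (Phi + Phi.T)


def fit_efa(S: CorrelationStructure, k: int, rotation: str = "oblimin",
            seed: int = 0) -> FactorSolution:
    """Minres extraction + oblimin rotation on an observed correlation matrix.

    The matrix is repaired to the nearest PSD correlation first (rank-based
    matrices need not be PSD).  Variance-explained shares are the rotated
    sum-of-squared-loadings diag(Phi L'L)/p; their total equals
    tr(L Phi L')/p, which is rotation-invariant.
    """
    p = len(S.words)
    if not (1 <= k < p):
        raise ValueError(f"k must satisfy 1 <= k < p (got k={k}, p={p})")
    M = nearest_psd_correlation(S.matrix)
    L0 = _minres(M, k)
    if rotation == "oblimin":
        L, Phi = _rotate_oblimin(L0, seed=seed)
    elif rotation in (None, "none"):
        L, Phi = L0, np.eye(k)
    else:
        raise ValueError(f"unknown rotation {rotation!r}")
    L, Phi = _tidy_solution(L, Phi)
    ss = np.clip(np.diag(Phi @ L.T @ L), 0.0, None)
    props = ss / p
    variance = {
        "per_factor": props,
        "total": float(props.sum()),
    }
    return FactorSolution(
        k=k, loadings=L, factor_correlations=Phi,
        variance_explained=variance, rotation=rotation or "none",
        words=list(S.words),
    )


def implied_correlation_efa(solution: FactorSolution) -> CorrelationStructure:
    """Model-implied correlations R_hat = L Phi L' with unit diagonal."""
    L = np.asarray(solution.loadings, float)
    Phi = np.asarray(solution.factor_correlations, float)
    if L.shape[1] != Phi.shape[0]:
        raise ValueError("loadings and factor correlations disagree on k")
    R = L @ Phi @ L.T
    n_clip = int(np.sum((R < -1) | (R > 1)) - np.sum(np.diag(R) > 1))
    if n_clip > 0:
        import logging
        logging.getLogger("descnet").info(
            "implied_correlation_efa: clipped %d off-diagonal entr(ies)", n_clip
        )
    R = np.clip(R, -1.0, 1.0)
    np.fill_diagonal(R, 1.0)
    words = solution.words or [f"w{i:04d}" for i in range(L.shape[0])]
    return CorrelationStructure(words=list(words), matrix=0.5 * (R + R.T), kind="implied")
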