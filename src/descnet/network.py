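"""Sparse Gaussian graphical model (graphical lasso + EBIC) and network
descriptives: partial-correlation edges, strength centrality, Louvain
communities, and four-timepoint centrality dynamics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Optional

import networkx as nx
import numpy as np

from ._glasso import GlassoPath, ggm_refit
from ._utils import check_symmetric, nearest_psd_correlation
from .textprep import (
    CorrelationStructure,
    DocumentTermMatrix,
    Vocabulary,
    build_dtm,
    prepare_correlation,
)
from .io import DescriptionTable

logger = logging.getLogger("descnet")

EDGE_EPS = 1e-8  # numerical floor: |partial| above this counts as an edge


@dataclass
class SnmSettings:
    """Graphical-lasso path configuration.

    lambda values run log-spaced from lambda_max = max |off-diag S| down to
    lambda_min_ratio * lambda_max.  ``patience``: stop descending once EBIC
    has strictly worsened that many times since the last improvement
    (None = full grid).
    """

    gamma: float = 0.25
    n_lambdas: int = 100
    lambda_min_ratio: float = 0.01
    tol: float = 1e-5
    max_iter: int = 200
    patience: Optional[int] = None
    refit: bool = True  # unpenalized GGM MLE on the selected support


@dataclass
class NetworkSolution:
    words: list
    precision: np.ndarray
    partials: np.ndarray
    lambda_: float
    gamma: float
    n_effective: int
    edge_count: int

    def __post_init__(self) -> None:
        K = self.precision
        if np.linalg.eigvalsh(K).min() <= 0:
            raise ValueError("precision matrix must be positive definite")
        iu = np.triu_indices(K.shape[0], 1)
        if self.edge_count != int(np.sum(np.abs(self.partials[iu]) > EDGE_EPS)):
            raise ValueError("edge_count inconsistent with partials")


def partials_from_precision(K: np.ndarray) -> np.ndarray:
    d = np.sqrt(np.diag(K))
    P = -K / np.outer(d, d)
    np.fill_diagonal(P, 0.0)
    return 0.5 * (P + P.T)


def ebic(K: np.ndarray, S: np.ndarray, n: int, gamma: float) -> float:
    """EBIC = -2 l(K) + E log n + 4 E gamma log p with
    l = (n/2)(log det K - tr(S K))."""
    p = K.shape[0]
    sign, logdet = np.linalg.slogdet(K)
    if sign <= 0:
        return np.inf
    ll = 0.5 * n * (logdet - float(np.sum(S * K)))
    iu = np.triu_indices(p, 1)
    E = int(np.sum(np.abs(K[iu]) > EDGE_EPS))
    return -2.0 * ll + E * np.log(n) + 4.0 * E * gamma * np.log(p)


def fit_snm(
    S: CorrelationStructure,
    n: int,
    gamma: float = 0.25,
    settings: Optional[SnmSettings] = None,
) -> NetworkSolution:
    """EBIC-selected graphical lasso on an observed correlation matrix.

    The matrix is PSD-repaired, the lasso is solved along a descending
    log-spaced lambda grid with warm starts, and the EBIC-minimizing
    precision is returned (ties break toward the larger lambda, i.e. the
    sparser model).
    """
    if n < 10:
        raise ValueError("need n >= 10 observations")
    if settings is None:
        settings = SnmSettings(gamma=gamma)
    M = nearest_psd_correlation(S.matrix, eps=1e-4)
    p = M.shape[0]
    lam_max = float(np.max(np.abs(M - np.eye(p))))
    if lam_max <= 0:
        lam_max = 1e-3
    lams = np.geomspace(lam_max, settings.lambda_min_ratio * lam_max,
                        settings.n_lambdas)
    path = GlassoPath(M, tol=settings.tol, max_iter=settings.max_iter)
    best = None
    worse = 0
    diagnostics = []
    seen_supports: dict = {}
    for lam in lams:
        try:
            K = path.solve(lam)
        except FloatingPointError as exc:
            diagnostics.append((float(lam), str(exc)))
            continue
        if settings.refit:
            # score each distinct support by its unpenalized (relaxed) MLE,
            # so edge inclusion is judged free of shrinkage bias
            support = np.abs(partials_from_precision(K)) > EDGE_EPS
            key = support.tobytes()
            if key in seen_supports:
                score = seen_supports[key]
            else:
                try:
                    K = ggm_refit(M, support)
                    score = ebic(K, M, n, settings.gamma)
                except FloatingPointError as exc:
                    diagnostics.append((float(lam), str(exc)))
                    continue
                seen_supports[key] = score
        else:
            score = ebic(K, M, n, settings.gamma)
        if not np.isfinite(score):
            diagnostics.append((float(lam), "non-finite EBIC"))
            continue
        if best is None or score < best[0] - 1e-9:
            best = (score, float(lam), K.copy())
            worse = 0
        elif score > best[0] + 1e-9:
            worse += 1
            if settings.patience is not None and worse >= settings.patience:
                break
    if best is None:
        raise RuntimeError(f"no lambda converged; per-lambda diagnostics: {diagnostics}")
    _, lam_sel, K = best
    P = partials_from_precision(K)
    iu = np.triu_indices(p, 1)
    E = int(np.sum(np.abs(P[iu]) > EDGE_EPS))
    # zero out sub-floor noise so edge_count matches strictly nonzero entries
    P[np.abs(P) <= EDGE_EPS] = 0.0
    return NetworkSolution(
        words=list(S.words), precision=K, partials=P,
        lambda_=lam_sel, gamma=settings.gamma, n_effective=n, edge_count=E,
    )


def implied_correlation_snm(solution: NetworkSolution) -> CorrelationStructure:
    """Invert the precision matrix and rescale to a correlation matrix."""
    K = solution.precision
    w = np.linalg.eigvalsh(K)
    if w.min() <= 0:
        raise np.linalg.LinAlgError("precision matrix is singular")
    Sigma = np.linalg.inv(K)
    d = np.sqrt(np.diag(Sigma))
    R = Sigma / np.outer(d, d)
    np.fill_diagonal(R, 1.0)
    R = np.clip(0.5 * (R + R.T), -1.0, 1.0)
    return CorrelationStructure(
        words=list(solution.words), matrix=R, kind="implied",
        n_effective=solution.n_effective,
    )


def strength_centrality(weights: np.ndarray) -> np.ndarray:
    """s_i = sum_j |w_ij| over a symmetric zero-diagonal weight matrix."""
    W = check_symmetric(weights, tol=1e-10, what="weight matrix")
    W = W.copy()
    np.fill_diagonal(W, 0.0)
    return np.abs(W).sum(axis=1)


@dataclass
class CommunityPartition:
    assignment: Dict[object, int]
    modularity: float
    resolution: float
    seed: int
    n_communities: int = 0

    def __post_init__(self) -> None:
        self.n_communities = len(set(self.assignment.values()))


def detect_communities(
    R: CorrelationStructure,
    resolution: float = 1.0,
    seed: int = 0,
    edge_floor: float = 0.0,
) -> CommunityPartition:
    """Louvain modularity communities of the implied correlation network.

    Modularity needs nonnegative weights, so negative entries are dropped;
    ``edge_floor`` optionally removes weak edges (e.g. 0.10 for display-
    style thresholding).
    """
    W = R.matrix.copy()
    np.fill_diagonal(W, 0.0)
    G = nx.Graph()
    G.add_nodes_from(R.words)
    p = len(R.words)
    iu, ju = np.triu_indices(p, 1)
    for i, j in zip(iu, ju):
        w = W[i, j]
        if w > edge_floor:
            G.add_edge(R.words[i], R.words[j], weight=float(w))
    if G.number_of_edges() == 0:
        raise ValueError("graph is empty after dropping negative/floored edges")
    comms = nx.community.louvain_communities(G, weight="weight", seed=seed,
                                             resolution=resolution)
    Q = nx.community.modularity(G, comms, weight="weight", resolution=resolution)
    assignment = {}
    for cid, nodes in enumerate(comms):
        for node in nodes:
            assignment[node] = cid
    for node in R.words:  # isolated nodes: singleton communities
        if node not in assignment:
            assignment[node] = len(assignment)
    return CommunityPartition(assignment=assignment, modularity=float(Q),
                              resolution=resolution, seed=seed)


@dataclass
class CentralityTrajectory:
    time_points: list
    centrality: list          # per timepoint: dict word -> strength
    delta: list               # per timepoint (None at t1): dict word -> change
    vocabulary_sizes: list


TIMEPOINT_LABELS = ["t1", "t2", "t3", "t4"]


def _timepoint_dtm(table: DescriptionTable, vocab: Vocabulary, t: int
                   ) -> DocumentTermMatrix:
    # t1: first word of pause 1; t2: rest of pause 1; t3: pause 2; t4: pause 3
    if t == 0:
        return build_dtm(table, vocab, pauses=(1,), first_word_only=True)
    if t == 1:
        df = table.records
        sub = DescriptionTable(
            df.loc[(df["pause"] == 1) & (df["position"] >= 2)].copy(),
            provenance=table.provenance,
        )
        return build_dtm(sub, vocab, pauses=(1,))
    return build_dtm(table, vocab, pauses=(t,))


def temporal_centrality_dynamics(
    table: DescriptionTable,
    vocab: Vocabulary,
    snm_settings: Optional[SnmSettings] = None,
) -> CentralityTrajectory:
    """Per-timepoint sparse networks and strength-centrality changes.

    Four disjoint word sets are modeled: the first word of pause 1, the
    remaining pause-1 words, pause-2 words, and pause-3 words.  Each
    timepoint's network covers the words actually present then; centrality
    is the strength on the implied correlation matrix, and deltas compare
    consecutive timepoints with absent-at-previous words baselined at 0.
    """
    cents: list = []
    sizes: list = []
    for t in range(4):
        dtm = _timepoint_dtm(table, vocab, t)
        present = dtm.values.max(axis=0) > dtm.values.min(axis=0)
        if present.sum() < 3:
            raise ValueError(
                f"timepoint {TIMEPOINT_LABELS[t]} has fewer than 3 usable words"
            )
        sub = DocumentTermMatrix(
            videos=dtm.videos,
            words=[w for w, m in zip(dtm.words, present) if m],
            values=dtm.values[:, present],
        )
        S = prepare_correlation(sub)
        sol = fit_snm(S, n=len(sub.videos), settings=snm_settings)
        R = implied_correlation_snm(sol)
        W = R.matrix.copy()
        np.fill_diagonal(W, 0.0)
        s = strength_centrality(W)
        cents.append(dict(zip(R.words, s)))
        sizes.append(len(R.words))
    deltas: list = [None]
    for t in range(1, 4):
        prev, cur = cents[t - 1], cents[t]
        deltas.append({w: c - prev.get(w, 0.0) for w, c in cur.items()})
    return CentralityTrajectory(
        time_points=list(TIMEPOINT_LABELS),
        centrality=cents,
        delta=deltas,
        vocabulary_sizes=sizes,
    )
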