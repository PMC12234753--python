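"""Synthetic free-description corpora with known ground truth.

Counts are generated through a Gaussian copula: video-level latent scores
are drawn multivariate-normal with a correlation structure implied either
by a common-factor model (loadings + factor correlations + uniquenesses)
or by a sparse precision matrix, and each word's latent margin is pushed
through the zero-inflated negative-binomial quantile function.  The
monotone link approximately preserves the latent correlation ordering,
which is exactly the regime where the pipeline's rank-based (Spearman)
step is well-behaved.  Ground truth is always returned alongside the data
so recovery tests never re-derive it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import stats

from ._utils import child_seed
from .io import DescriptionTable
from .network import partials_from_precision
from .textprep import DocumentTermMatrix


# ---------------------------------------------------------------------------
# structures and specs
# ---------------------------------------------------------------------------

@dataclass
class FactorStructure:
    """Common-factor truth: p x k loadings and k x k factor correlations.

    Uniquenesses are 1 - diag(L Phi L'), so the latent covariance is a
    correlation matrix.
    """

    loadings: np.ndarray
    factor_corr: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.loadings = np.atleast_2d(np.asarray(self.loadings, float))
        k = self.loadings.shape[1]
        if self.factor_corr is None:
            self.factor_corr = np.eye(k)
        self.factor_corr = np.asarray(self.factor_corr, float)
        if self.factor_corr.shape != (k, k):
            raise ValueError("factor_corr must be k x k")
        if np.linalg.eigvalsh(self.factor_corr).min() < -1e-10:
            raise ValueError("factor_corr must be PSD")
        common = np.diag(self.loadings @ self.factor_corr @ self.loadings.T)
        if (common > 1 + 1e-10).any():
            raise ValueError("communalities exceed 1; invalid loadings")

    def latent_correlation(self) -> np.ndarray:
        C = self.loadings @ self.factor_corr @ self.loadings.T
        np.fill_diagonal(C, 1.0)
        return 0.5 * (C + C.T)


@dataclass
class NetworkStructure:
    """Sparse-precision truth K (symmetric positive definite)."""

    precision: np.ndarray

    def __post_init__(self) -> None:
        K = np.asarray(self.precision, float)
        if np.max(np.abs(K - K.T)) > 1e-10:
            raise ValueError("precision must be symmetric")
        if np.linalg.eigvalsh(K).min() <= 0:
            raise ValueError("precision must be positive definite")
        self.precision = 0.5 * (K + K.T)

    def latent_correlation(self) -> np.ndarray:
        Sigma = np.linalg.inv(self.precision)
        d = np.sqrt(np.diag(Sigma))
        C = Sigma / np.outer(d, d)
        np.fill_diagonal(C, 1.0)
        return 0.5 * (C + C.T)

    def partials(self) -> np.ndarray:
        return partials_from_precision(self.precision)


@dataclass
class CountLink:
    """Zero-inflated negative-binomial margin for the copula counts."""

    zero_inflation: float = 0.3
    nb_mean: float = 2.0
    nb_dispersion: float = 3.0  # NB size parameter r; variance = mu + mu^2/r

    def __post_init__(self) -> None:
        if not (0 <= self.zero_inflation < 1):
            raise ValueError("zero_inflation must be in [0, 1)")
        if self.nb_mean <= 0 or self.nb_dispersion <= 0:
            raise ValueError("nb_mean and nb_dispersion must be positive")

    def _nb_p(self) -> float:
        return self.nb_dispersion / (self.nb_dispersion + self.nb_mean)

    def quantile(self, u: np.ndarray) -> np.ndarray:
        """ZINB quantile function applied elementwise to uniforms."""
        pi0 = self.zero_inflation
        out = np.zeros_like(u)
        mask = u >= pi0
        if mask.any():
            v = np.clip((u[mask] - pi0) / (1 - pi0), 0.0, 1.0 - 1e-12)
            out[mask] = stats.nbinom.ppf(v, self.nb_dispersion, self._nb_p())
        return out

    def zero_fraction(self) -> float:
        """Theoretical marginal P(count = 0)."""
        nb0 = stats.nbinom.pmf(0, self.nb_dispersion, self._nb_p())
        return self.zero_inflation + (1 - self.zero_inflation) * nb0


Structure = Union[FactorStructure, NetworkStructure]


@dataclass
class SyntheticSpec:
    """Study conditions for a synthetic corpus.

    Defaults mirror the free-description design being emulated: 44
    participants per video, 3 pauses, and 2.91 words per pause (SD 2.34).
    """

    n_videos: int
    vocab_size: int
    structure: Structure
    participants_per_video: int = 44
    pauses: int = 3
    words_per_pause_mean: float = 2.91
    words_per_pause_sd: float = 2.34
    count_link: CountLink = field(default_factory=CountLink)
    seed: int = 0

    def __post_init__(self) -> None:
        p = self.vocab_size
        dim = (
            self.structure.loadings.shape[0]
            if isinstance(self.structure, FactorStructure)
            else self.structure.precision.shape[0]
        )
        if dim != p:
            raise ValueError(f"structure dimension {dim} != vocab_size {p}")


@dataclass
class SyntheticTruth:
    structure: Structure
    latent_correlation: np.ndarray
    seed: int
    edge_deltas: Optional[list] = None
    temporal_shift: Optional[tuple] = None


def word_labels(p: int) -> List[str]:
    return [f"w{i + 1:04d}" for i in range(p)]


def video_labels(n: int) -> List[str]:
    return [f"v{i + 1:04d}" for i in range(n)]


# ---------------------------------------------------------------------------
# count-matrix generators
# ---------------------------------------------------------------------------

def _latent_draw(C: np.ndarray, n: int, rng: np.random.Generator) -> np.ndarray:
    w, V = np.linalg.eigh(C)
    A = V * np.sqrt(np.clip(w, 0.0, None))
    return rng.standard_normal((n, C.shape[0])) @ A.T


def _copula_counts(C: np.ndarray, n: int, link: CountLink,
                   rng: np.random.Generator) -> np.ndarray:
    Y = _latent_draw(C, n, rng)
    return link.quantile(stats.norm.cdf(Y))


def generate_factor_corpus(spec: SyntheticSpec) -> Tuple[DocumentTermMatrix, SyntheticTruth]:
    """Counts whose latent structure is a common-factor model."""
    if not isinstance(spec.structure, FactorStructure):
        raise ValueError("spec.structure must be a FactorStructure")
    C = spec.structure.latent_correlation()
    rng = np.random.default_rng(spec.seed)
    X = _copula_counts(C, spec.n_videos, spec.count_link, rng)
    dtm = DocumentTermMatrix(
        videos=video_labels(spec.n_videos), words=word_labels(spec.vocab_size),
        values=X,
    )
    return dtm, SyntheticTruth(structure=spec.structure, latent_correlation=C,
                               seed=spec.seed)


def generate_network_corpus(spec: SyntheticSpec) -> Tuple[DocumentTermMatrix, SyntheticTruth]:
    """Counts whose latent structure is a sparse Gaussian graphical model."""
    if not isinstance(spec.structure, NetworkStructure):
        raise ValueError("spec.structure must be a NetworkStructure")
    C = spec.structure.latent_correlation()
    rng = np.random.default_rng(spec.seed)
    X = _copula_counts(C, spec.n_videos, spec.count_link, rng)
    dtm = DocumentTermMatrix(
        videos=video_labels(spec.n_videos), words=word_labels(spec.vocab_size),
        values=X,
    )
    return dtm, SyntheticTruth(structure=spec.structure, latent_correlation=C,
                               seed=spec.seed)


def _shift_partials(K: np.ndarray, edge_deltas: Sequence[tuple]) -> np.ndarray:
    """Return K with the listed pairs' partial correlations shifted by delta."""
    K2 = K.copy()
    for (i, j, delta) in edge_deltas:
        pij = -K[i, j] / np.sqrt(K[i, i] * K[j, j])
        target = pij + delta
        if not (-1 < target < 1):
            raise ValueError(f"pair ({i},{j}): shifted partial {target:.3f} outside (-1,1)")
        K2[i, j] = K2[j, i] = -target * np.sqrt(K[i, i] * K[j, j])
    if np.linalg.eigvalsh(K2).min() <= 0:
        bad = ", ".join(f"({i},{j})" for i, j, _ in edge_deltas)
        raise ValueError(f"perturbation breaks positive definiteness (pairs {bad})")
    return K2


def generate_two_population(
    spec: SyntheticSpec, edge_deltas: Sequence[tuple]
) -> Tuple[DocumentTermMatrix, DocumentTermMatrix, SyntheticTruth]:
    """Two corpora from one law except listed partial-correlation shifts.

    edge_deltas: (word_index_i, word_index_j, delta_partial) triples applied
    to population B's precision matrix.
    """
    if not isinstance(spec.structure, NetworkStructure):
        raise ValueError("spec.structure must be a NetworkStructure")
    K_a = spec.structure.precision
    K_b = _shift_partials(K_a, edge_deltas)
    struct_b = NetworkStructure(precision=K_b)
    rng_a = np.random.default_rng(child_seed(spec.seed, 1))
    rng_b = np.random.default_rng(child_seed(spec.seed, 2))
    Xa = _copula_counts(spec.structure.latent_correlation(), spec.n_videos,
                        spec.count_link, rng_a)
    Xb = _copula_counts(struct_b.latent_correlation(), spec.n_videos,
                        spec.count_link, rng_b)
    words = word_labels(spec.vocab_size)
    dtm_a = DocumentTermMatrix(videos=video_labels(spec.n_videos), words=words,
                               values=Xa)
    dtm_b = DocumentTermMatrix(videos=video_labels(spec.n_videos), words=words,
                               values=Xb)
    truth = SyntheticTruth(
        structure=spec.structure,
        latent_correlation=spec.structure.latent_correlation(),
        seed=spec.seed, edge_deltas=list(edge_deltas),
    )
    return dtm_a, dtm_b, truth


# ---------------------------------------------------------------------------
# description-table generators
# ---------------------------------------------------------------------------

def _words_per_pause(spec: SyntheticSpec, size: int,
                     rng: np.random.Generator) -> np.ndarray:
    """Per-(participant, pause) word counts: negative binomial matched to the
    target mean/SD, truncated at the ten response boxes."""
    mu, sd = spec.words_per_pause_mean, spec.words_per_pause_sd
    var = sd * sd
    if var > mu:
        r = mu * mu / (var - mu)
        m = rng.negative_binomial(r, r / (r + mu), size=size)
    else:
        m = rng.poisson(mu, size=size)
    return np.minimum(m, 10)


def generate_description_table(spec: SyntheticSpec) -> Tuple[DescriptionTable, SyntheticTruth]:
    """Long-format description table with per-pause word counts drawn from
    the study's NB(2.91, SD 2.34) regime; word identities follow per-video
    multinomial weights derived from the latent structure."""
    C = spec.structure.latent_correlation()
    rng = np.random.default_rng(spec.seed)
    Y = _latent_draw(C, spec.n_videos, rng)
    weights = np.exp(Y)  # video-level word propensities, monotone in latent
    weights /= weights.sum(axis=1, keepdims=True)
    words = word_labels(spec.vocab_size)
    videos = video_labels(spec.n_videos)
    rows = []
    for vi, video in enumerate(videos):
        for pi in range(spec.participants_per_video):
            participant = f"{video}_p{pi + 1:03d}"
            counts = _words_per_pause(spec, spec.pauses, rng)
            for pause in range(1, spec.pauses + 1):
                m = int(counts[pause - 1])
                if m == 0:
                    continue
                picks = rng.choice(spec.vocab_size, size=m, p=weights[vi])
                for pos, wi in enumerate(picks, start=1):
                    rows.append((participant, video, pause, pos, words[wi]))
    df = pd.DataFrame(rows, columns=["participant", "video", "pause", "position",
                                     "word"])
    table = DescriptionTable(df, provenance=f"synthetic(seed={spec.seed})")
    truth = SyntheticTruth(structure=spec.structure, latent_correlation=C,
                           seed=spec.seed)
    return table, truth


def generate_temporal_corpus(
    spec: SyntheticSpec,
    shift: Optional[Tuple[int, int, float]] = None,
) -> Tuple[DescriptionTable, SyntheticTruth]:
    """Description table with the four-timepoint split well-defined.

    Timepoints: t1 = first word of pause 1, t2 = later pause-1 words,
    t3 = pause 2, t4 = pause 3.  All four share the same latent network
    except an optional planted strengthening ``shift = (word_index,
    timepoint in {2,3,4}, factor)`` multiplying that word's off-diagonal
    precision entries at that timepoint.
    """
    if not isinstance(spec.structure, NetworkStructure):
        raise ValueError("spec.structure must be a NetworkStructure")
    if shift is not None and shift[1] not in (2, 3, 4):
        raise ValueError("shift timepoint must be in {2, 3, 4}")
    K = spec.structure.precision
    p = spec.vocab_size
    structures = []
    for t in range(1, 5):
        if shift is not None and t == shift[1]:
            wi, _, factor = shift
            K_t = K.copy()
            row = K[wi].copy() * factor
            row[wi] = K[wi, wi]
            K_t[wi, :] = row
            K_t[:, wi] = row
            if np.linalg.eigvalsh(K_t).min() <= 0:
                raise ValueError("temporal strengthening breaks positive definiteness")
            structures.append(NetworkStructure(precision=K_t))
        else:
            structures.append(spec.structure)
    words = word_labels(p)
    videos = video_labels(spec.n_videos)
    npart = spec.participants_per_video
    rows = []
    rng = np.random.default_rng(spec.seed)
    # timepoint -> (pause, starting position)
    placement = {0: (1, 1), 1: (1, 2), 2: (2, 1), 3: (3, 1)}
    for t in range(4):
        C_t = structures[t].latent_correlation()
        rng_t = np.random.default_rng(child_seed(spec.seed, 10 + t))
        X_t = _copula_counts(C_t, spec.n_videos, spec.count_link, rng_t)
        pause, pos0 = placement[t]
        for vi, video in enumerate(videos):
            tokens = np.repeat(np.arange(p), X_t[vi].astype(int))
            rng.shuffle(tokens)
            if t == 0:
                tokens = tokens[:npart]  # one first-word slot per participant
                for pi, wi in enumerate(tokens):
                    rows.append((f"{video}_p{pi + 1:03d}", video, pause, 1,
                                 words[wi]))
            else:
                pos_counter = np.full(npart, pos0)
                for ti, wi in enumerate(tokens):
                    pi = ti % npart
                    rows.append((f"{video}_p{pi + 1:03d}", video, pause,
                                 int(pos_counter[pi]), words[wi]))
                    pos_counter[pi] += 1
    df = pd.DataFrame(rows, columns=["participant", "video", "pause", "position",
                                     "word"])
    df = df.sort_values(["video", "participant", "pause", "position"],
                        kind="stable").reset_index(drop=True)
    table = DescriptionTable(df, provenance=f"synthetic-temporal(seed={spec.seed})")
    table.validate()
    truth = SyntheticTruth(
        structure=spec.structure,
        latent_correlation=spec.structure.latent_correlation(),
        seed=spec.seed, temporal_shift=shift,
    )
    return table, truth


# ---------------------------------------------------------------------------
# convenience truths
# ---------------------------------------------------------------------------

def equal_loading_factors(p: int, k: int, loading: float = 0.7,
                          phi: float = 0.0) -> FactorStructure:
    """Simple-structure loadings: p/k words per factor at a common loading,
    constant inter-factor correlation phi."""
    L = np.zeros((p, k))
    per = p // k
    for j in range(k):
        lo = j * per
        hi = (j + 1) * per if j < k - 1 else p
        L[lo:hi, j] = loading
    Phi = np.full((k, k), phi)
    np.fill_diagonal(Phi, 1.0)
    return FactorStructure(loadings=L, factor_corr=Phi)


def chain_precision(p: int, partial: float = 0.35) -> NetworkStructure:
    """First-order chain: unit diagonal, adjacent partial correlations."""
    K = np.eye(p)
    for i in range(p - 1):
        K[i, i + 1] = K[i + 1, i] = -partial
    return NetworkStructure(precision=K)


def random_sparse_precision(p: int, density: float = 0.1,
                            partial: float = 0.3, seed: int = 0) -> NetworkStructure:
    """Random sparse precision with edges at +-partial, diagonally loaded
    until positive definite."""
    rng = np.random.default_rng(seed)
    U = np.zeros((p, p))
    iu = np.triu_indices(p, 1)
    mask = rng.random(len(iu[0])) < density
    signs = rng.choice([-1.0, 1.0], size=len(iu[0]))
    U[iu] = np.where(mask, -signs * partial, 0.0)
    K = U + U.T + np.eye(p)
    w = np.linalg.eigvalsh(K).min()
    if w <= 0.05:
        K = K + (0.05 - w) * np.eye(p)
        d = np.sqrt(np.diag(K))
        K = K / np.outer(d, d)
    return NetworkStructure(precision=K)
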