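"""Cleaning, vocabulary filtering, and the document-term pipeline.

The pipeline mirrors how sparse free-description data are prepared for
co-occurrence modeling: lemmatize and screen tokens, drop words mentioned
by a single participant or in under a fraction of the videos, tally
per-video mention frequencies, min-max normalize each word column (to
absorb unequal rater counts per video), Gaussianize marginals with a
Winsorized-ECDF nonparanormal transform, and compute the Spearman
correlation matrix between words.  Because min-max scaling and the
nonparanormal map are columnwise monotone, the Spearman matrix is
invariant to them whenever tie structure is preserved; the transforms are
kept because downstream Gaussian models (factor analysis, graphical
lasso) assume approximately normal margins.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Dict, Iterable, Optional, Sequence

import numpy as np
from scipy import stats

from ._utils import spearman_corr
from .io import DescriptionTable
from .lemma import lemmatize, spell_correct

logger = logging.getLogger("descnet")


@dataclass
class Vocabulary:
    words: list
    video_counts: np.ndarray
    participant_counts: np.ndarray

    def __post_init__(self) -> None:
        if len(set(self.words)) != len(self.words):
            raise ValueError("vocabulary words must be unique")
        self.video_counts = np.asarray(self.video_counts, dtype=int)
        self.participant_counts = np.asarray(self.participant_counts, dtype=int)
        if not (
            len(self.words) == len(self.video_counts) == len(self.participant_counts)
        ):
            raise ValueError("words and count vectors must align")

    def __len__(self) -> int:
        return len(self.words)


@dataclass
class DocumentTermMatrix:
    """videos x words frequency matrix with an explicit normalization state."""

    videos: list
    words: list
    values: np.ndarray
    state: str = "counts"  # counts | minmax | nonparanormal

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.videos), len(self.words)):
            raise ValueError("values shape must be (n_videos, n_words)")
        if self.state not in ("counts", "minmax", "nonparanormal"):
            raise ValueError(f"unknown state {self.state!r}")
        if self.state == "counts":
            if (self.values < 0).any() or np.any(self.values != np.round(self.values)):
                raise ValueError("counts state requires nonnegative integers")

    @property
    def shape(self):
        return self.values.shape


@dataclass
class CorrelationStructure:
    """Symmetric unit-diagonal correlation matrix over a word ordering."""

    words: list
    matrix: np.ndarray
    kind: str = "observed"  # observed | implied
    n_effective: int = 0

    def __post_init__(self) -> None:
        M = np.asarray(self.matrix, dtype=float)
        if M.shape != (len(self.words), len(self.words)):
            raise ValueError("matrix shape must match words")
        if np.max(np.abs(M - M.T)) > 1e-12:
            raise ValueError("correlation matrix must be symmetric to 1e-12")
        if np.max(np.abs(np.diag(M) - 1.0)) > 1e-8:
            raise ValueError("correlation matrix diagonal must be 1")
        np.fill_diagonal(M, 1.0)  # snap float fuzz so the invariant is exact
        if M.min() < -1 or M.max() > 1:
            raise ValueError("correlation entries must lie in [-1, 1]")
        self.matrix = M


@dataclass
class CleaningPolicy:
    """What preprocess_words does: lemmatize, lexicon-screen, spell-correct."""

    lemmatize: bool = True
    screen_lexicon: bool = True
    spell_correct: bool = False


def preprocess_words(
    table: DescriptionTable,
    lexicon: Optional[Iterable[str]] = None,
    policy: CleaningPolicy = CleaningPolicy(),
) -> DescriptionTable:
    """Lemmatize tokens and remove those failing the lexicon screen.

    Words with no lexicon entry (after optional edit-distance-1 spell
    repair) are treated as meaningless and dropped; removal counts are
    recorded per reason.
    """
    lex = frozenset(w.strip().lower() for w in lexicon) if lexicon is not None else None
    if policy.screen_lexicon and not lex:
        raise ValueError("lexicon must be nonempty when screening is enabled")
    df = table.records.copy()
    counts: Dict[str, int] = dict(table.removal_counts)
    words = df["word"].tolist()
    out = []
    keep = np.ones(len(words), dtype=bool)
    n_spell = 0
    for i, w in enumerate(words):
        if policy.spell_correct and lex is not None and w not in lex:
            fixed = spell_correct(w, lex)
            if fixed is not None:
                w = fixed
                n_spell += 1
        lemma = lemmatize(w, lex) if policy.lemmatize else w
        if policy.screen_lexicon and lemma not in lex and w not in lex:
            keep[i] = False
        out.append(lemma)
    df["word"] = out
    removed = int((~keep).sum())
    df = df.loc[keep]
    counts["not_in_lexicon"] = counts.get("not_in_lexicon", 0) + removed
    if n_spell:
        counts["spell_corrected"] = counts.get("spell_corrected", 0) + n_spell
    if removed:
        logger.info("preprocess_words: removed %d out-of-lexicon token(s)", removed)
    return DescriptionTable(df, provenance=table.provenance, removal_counts=counts)


def filter_vocabulary(
    table: DescriptionTable,
    min_participants: int = 2,
    min_video_fraction: float = 0.01,
) -> Vocabulary:
    """Retain words mentioned by >= min_participants distinct participants
    AND in >= ceil(min_video_fraction * n_videos) distinct videos."""
    if not (0 < min_video_fraction <= 1):
        raise ValueError("min_video_fraction must be in (0, 1]")
    df = table.records
    if df.empty:
        raise ValueError("cannot build a vocabulary from an empty table")
    n_videos = df["video"].nunique()
    video_threshold = math.ceil(min_video_fraction * n_videos)
    g = df.groupby("word")
    vid_counts = g["video"].nunique()
    part_counts = g["participant"].nunique()
    keep = (part_counts >= min_participants) & (vid_counts >= video_threshold)
    words = sorted(keep.index[keep])
    return Vocabulary(
        words=words,
        video_counts=vid_counts.loc[words].to_numpy(),
        participant_counts=part_counts.loc[words].to_numpy(),
    )


def build_dtm(
    table: DescriptionTable,
    vocab: Vocabulary,
    pauses: Sequence[int] = (1, 2, 3),
    first_word_only: bool = False,
) -> DocumentTermMatrix:
    """Tally per-video mention counts of retained words within the pause
    filter (optionally only the first word of each pause)."""
    if len(vocab) == 0:
        raise ValueError("vocabulary is empty")
    df = table.records
    mask = df["pause"].isin(list(pauses))
    if first_word_only:
        mask &= df["position"] == 1
    df = df.loc[mask & df["word"].isin(vocab.words)]
    videos = table.videos()
    vindex = {v: i for i, v in enumerate(videos)}
    windex = {w: j for j, w in enumerate(vocab.words)}
    F = np.zeros((len(videos), len(vocab.words)))
    for v, w in zip(df["video"], df["word"]):
        F[vindex[v], windex[w]] += 1
    return DocumentTermMatrix(videos=videos, words=list(vocab.words), values=F)


def normalize_dtm(dtm: DocumentTermMatrix) -> DocumentTermMatrix:
    """Columnwise min-max normalization; constant columns are dropped."""
    if dtm.state != "counts":
        raise ValueError("normalize_dtm expects a counts-state matrix")
    X = dtm.values
    lo, hi = X.min(axis=0), X.max(axis=0)
    const = hi == lo
    if const.all():
        raise ValueError("all columns are constant; degenerate corpus")
    if const.any():
        dropped = [w for w, c in zip(dtm.words, const) if c]
        logger.warning("normalize_dtm: dropping %d constant column(s): %s",
                       len(dropped), ", ".join(map(str, dropped[:10])))
    keep = ~const
    Xn = (X[:, keep] - lo[keep]) / (hi[keep] - lo[keep])
    return DocumentTermMatrix(
        videos=dtm.videos,
        words=[w for w, k in zip(dtm.words, keep) if k],
        values=Xn,
        state="minmax",
    )


def winsorization_level(n: int) -> float:
    """Truncation level delta_n = 1 / (4 n^{1/4} sqrt(pi log n))."""
    return 1.0 / (4.0 * n**0.25 * math.sqrt(math.pi * math.log(n)))


def nonparanormal(dtm: DocumentTermMatrix) -> DocumentTermMatrix:
    """Winsorized-ECDF Gaussianization of each column.

    z = Phi^{-1}(clip(rank/(n+1), delta_n, 1-delta_n)) with average ranks,
    so ties map to identical outputs and the transform is monotone in rank.
    """
    if dtm.state != "minmax":
        raise ValueError("nonparanormal expects a minmax-state matrix")
    n = dtm.values.shape[0]
    if n < 4:
        raise ValueError("nonparanormal transform needs at least 4 rows")
    delta = winsorization_level(n)
    Z = np.empty_like(dtm.values)
    for j in range(dtm.values.shape[1]):
        r = stats.rankdata(dtm.values[:, j], method="average")
        u = np.clip(r / (n + 1.0), delta, 1.0 - delta)
        Z[:, j] = stats.norm.ppf(u)
    return DocumentTermMatrix(
        videos=dtm.videos, words=list(dtm.words), values=Z, state="nonparanormal"
    )


def spearman_matrix(
    dtm: DocumentTermMatrix, on_constant: str = "error"
) -> CorrelationStructure:
    """Pairwise Spearman correlations between word columns (average-rank ties)."""
    C = spearman_corr(dtm.values, on_constant=on_constant)
    return CorrelationStructure(
        words=list(dtm.words), matrix=C, kind="observed",
        n_effective=dtm.values.shape[0],
    )


def prepare_correlation(
    dtm: DocumentTermMatrix, on_constant: str = "error"
) -> CorrelationStructure:
    """counts -> minmax -> nonparanormal -> Spearman, in one call."""
    return spearman_matrix(nonparanormal(normalize_dtm(dtm)), on_constant=on_constant)
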