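"""On-disk artifacts: description tables, matrices, networks, reports.

All text formats: CSV/TSV tables, edge-list CSV and GraphML for networks,
labeled TSV for correlation matrices, JSON for result reports, YAML for
pipeline configuration.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Dict, Optional

import networkx as nx
import numpy as np
import pandas as pd
import yaml

if TYPE_CHECKING:  # pragma: no cover
    from .network import NetworkSolution

logger = logging.getLogger("descnet")

REQUIRED_COLUMNS = ("participant", "video", "pause", "position", "word")
NETWORK_FORMATS = ("edgelist", "graphml")


class FormatError(ValueError):
    """A file does not match the declared dialect/columns."""


class ValidationError(ValueError):
    """A parsed record violates a domain invariant."""


@dataclass
class DescriptionTable:
    """Long-format free-description records.

    ``records`` columns: participant, video, pause (1-3), position (>=1,
    order within pause), word (non-empty lowercase token).
    """

    records: pd.DataFrame
    provenance: str = ""
    removal_counts: Dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        df = self.records
        missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"missing required column(s): {', '.join(missing)}")
        self.records = df.reset_index(drop=True)

    @property
    def n_records(self) -> int:
        return len(self.records)

    def videos(self) -> list:
        return sorted(self.records["video"].unique())

    def validate(self) -> None:
        df = self.records
        bad_pause = ~df["pause"].isin((1, 2, 3))
        if bad_pause.any():
            row = int(np.flatnonzero(bad_pause.to_numpy())[0])
            raise ValidationError(
                f"row {row}: pause={df['pause'].iloc[row]!r} not in {{1,2,3}}"
            )
        if (df["position"] < 1).any():
            row = int(np.flatnonzero((df["position"] < 1).to_numpy())[0])
            raise ValidationError(f"row {row}: position must be >= 1")
        key = df[["participant", "video", "pause", "position"]]
        if key.duplicated().any():
            row = int(np.flatnonzero(key.duplicated().to_numpy())[0])
            raise ValidationError(
                f"row {row}: duplicate (participant, video, pause, position) key"
            )


def read_descriptions(
    path, dialect: str = ",", provenance: Optional[str] = None
) -> DescriptionTable:
    """Read a long-format description table.

    The header row must name the five fields participant, video, pause,
    position, word.  Rows with an empty word cell are dropped (counted in
    the log); words are lowercased at read time.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=dialect, dtype={"participant": str, "video": str})
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(
            f"{path.name}: missing required column(s): {', '.join(missing)}"
        )
    df = df.loc[:, list(REQUIRED_COLUMNS)]
    word = df["word"].astype("string").str.strip().str.lower()
    blank = word.isna() | (word == "")
    n_dropped = int(blank.sum())
    if n_dropped:
        logger.info("read_descriptions: dropped %d blank-word row(s)", n_dropped)
    df = df.loc[~blank].copy()
    df["word"] = word[~blank].astype(str)
    bad = ~df["pause"].isin((1, 2, 3))
    if bad.any():
        row = int(df.index[bad][0])
        raise ValidationError(f"{path.name} row {row}: pause not in {{1,2,3}}")
    df["pause"] = df["pause"].astype(int)
    df["position"] = df["position"].astype(int)
    table = DescriptionTable(
        df, provenance=provenance or str(path), removal_counts={"blank_word": n_dropped}
    )
    table.validate()
    return table


def write_descriptions(table: DescriptionTable, path, dialect: str = ",") -> None:
    table.records.loc[:, list(REQUIRED_COLUMNS)].to_csv(path, sep=dialect, index=False)


def network_to_graph(solution: "NetworkSolution", precision: int = 6) -> nx.Graph:
    """Nonzero partial-correlation edges as a weighted undirected graph."""
    G = nx.Graph()
    G.add_nodes_from(solution.words)
    P = solution.partials
    words = solution.words
    iu, ju = np.triu_indices(len(words), k=1)
    for i, j in zip(iu, ju):
        w = round(float(P[i, j]), precision)
        if P[i, j] != 0.0 and w != 0.0:
            G.add_edge(words[i], words[j], weight=w)
    return G


def export_network(solution: "NetworkSolution", path, format: str = "edgelist") -> None:
    """Write nonzero edges (weight = partial correlation, 6 decimals)."""
    if format not in NETWORK_FORMATS:
        raise ValueError(
            f"unknown format {format!r}; supported formats: {', '.join(NETWORK_FORMATS)}"
        )
    path = Path(path)
    if format == "edgelist":
        P = solution.partials
        words = solution.words
        with open(path, "w") as fh:
            fh.write("source,target,weight\n")
            iu, ju = np.triu_indices(len(words), k=1)
            for i, j in zip(iu, ju):
                if P[i, j] != 0.0:
                    fh.write(f"{words[i]},{words[j]},{P[i, j]:.6f}\n")
    else:
        nx.write_graphml(network_to_graph(solution), path)


def read_network(path, format: str = "edgelist") -> nx.Graph:
    if format not in NETWORK_FORMATS:
        raise ValueError(
            f"unknown format {format!r}; supported formats: {', '.join(NETWORK_FORMATS)}"
        )
    if format == "edgelist":
        df = pd.read_csv(path, dtype={"source": str, "target": str})
        G = nx.Graph()
        for row in df.itertuples(index=False):
            G.add_edge(row.source, row.target, weight=float(row.weight))
        return G
    return nx.read_graphml(path)


def write_correlation(words, matrix: np.ndarray, path) -> None:
    pd.DataFrame(matrix, index=list(words), columns=list(words)).to_csv(path, sep="\t")


def read_correlation(path):
    df = pd.read_csv(path, sep="\t", index_col=0)
    return list(df.columns), df.to_numpy(dtype=float)


def write_dtm(videos, words, values: np.ndarray, path) -> None:
    pd.DataFrame(values, index=list(videos), columns=list(words)).to_csv(path)


def read_dtm(path):
    df = pd.read_csv(path, index_col=0)
    return [str(v) for v in df.index], list(df.columns), df.to_numpy(dtype=float)


class _ReportEncoder(json.JSONEncoder):
    def default(self, o):  # noqa: D102
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        return super().default(o)


def write_report(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, cls=_ReportEncoder)
        fh.write("\n")


def read_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)
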