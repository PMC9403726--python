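"""Data model and file I/O for connectomes, node tables and cohort tables.

A connectome is a weighted undirected brain graph: nodes are parcellated
brain regions (93 in the neonatal AAL-style parcellation used here) and
edge weights are nonnegative streamline-derived connectivity values
(e.g. sums of SIFT2 streamline weights).  Connectomes are stored on disk
as delimited-text square matrices; node and cohort metadata as delimited
tables with a header row.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Connectome",
    "Edge",
    "ValidationError",
    "AsymmetryError",
    "ShapeError",
    "NegativeWeightError",
    "NodeMismatchError",
    "read_connectome",
    "write_connectome",
    "read_node_table",
    "write_node_table",
    "read_cohort",
    "edge_list",
]

#: relative tolerance within which (i,j)/(j,i) discrepancies are averaged away
SYMMETRY_RTOL = 1e-8

REQUIRED_COHORT_COLUMNS = (
    "subject_id",
    "ga_birth",
    "pma_scan",
    "sex",
    "injury_rating",
    "cognitive_composite",
    "imd",
    "corrected_age_followup",
    "internalizing_raw",
    "externalizing_raw",
)


class ValidationError(ValueError):
    """Base class for connectome/table validation failures."""


class ShapeError(ValidationError):
    """Matrix is not square or does not match the node table."""


class AsymmetryError(ValidationError):
    """Matrix asymmetry exceeds the symmetry tolerance."""


class NegativeWeightError(ValidationError):
    """Matrix contains negative edge weights."""


class NodeMismatchError(ValidationError):
    """File node ids do not match the supplied node table."""


@dataclass(frozen=True)
class Edge:
    """An unordered weighted node pair; identity ignores endpoint order."""

    node_a: str
    node_b: str
    weight: float

    def __post_init__(self):
        if self.node_a == self.node_b:
            raise ValidationError(f"self-loop edge at node {self.node_a!r}")

    @property
    def pair(self) -> tuple[str, str]:
        return tuple(sorted((self.node_a, self.node_b)))

    def __eq__(self, other):
        if not isinstance(other, Edge):
            return NotImplemented
        return self.pair == other.pair and self.weight == other.weight

    def __hash__(self):
        return hash((self.pair, self.weight))


@dataclass
class Connectome:
    """One subject's weighted undirected brain graph.

    Parameters
    ----------
    subject_id : str
        Cohort-unique subject identifier.
    weights : ndarray of shape (N, N)
        Symmetric nonnegative edge-weight matrix with zero diagonal
        (streamline-weight units, dimensionless).
    node_ids : list of str
        Region identifiers, in row/column order of ``weights``.
    """

    subject_id: str
    weights: np.ndarray
    node_ids: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        self.node_ids = list(self.node_ids)
        validate_weights(self.weights, n_expected=len(self.node_ids))
        if len(set(self.node_ids)) != len(self.node_ids):
            raise ValidationError("node_ids are not unique")

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    def copy(self) -> "Connectome":
        return Connectome(self.subject_id, self.weights.copy(), list(self.node_ids))


def validate_weights(w: np.ndarray, n_expected: int | None = None) -> None:
    """Raise a specific :class:`ValidationError` subclass on any invariant breach."""
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise ShapeError(f"weight matrix is not square: shape {w.shape}")
    if n_expected is not None and w.shape[0] != n_expected:
        raise ShapeError(
            f"matrix has {w.shape[0]} nodes but {n_expected} node ids were given"
        )
    if not np.isfinite(w).all():
        raise ValidationError("weight matrix contains non-finite values")
    if (w < 0).any():
        raise NegativeWeightError("negative edge weights present")
    scale = max(np.abs(w).max(), 1.0)
    if np.abs(w - w.T).max() > SYMMETRY_RTOL * scale:
        raise AsymmetryError(
            "matrix asymmetry exceeds relative tolerance "
            f"{SYMMETRY_RTOL:g} (max |w - w.T| = {np.abs(w - w.T).max():g})"
        )
    if np.abs(np.diag(w)).max() > 0:
        raise ValidationError("nonzero diagonal (self-loops) present")


def _delimiter_for(path: str) -> str:
    return "\t" if str(path).endswith(".tsv") else ","


def read_connectome(
    path: str,
    node_table: pd.DataFrame | None = None,
    subject_id: str | None = None,
) -> Connectome:
    """Read a delimited-text square weight matrix as a :class:`Connectome`.

    The file may carry a header row of node ids; with a header and a
    ``node_table`` the columns are reordered to node-table order, otherwise
    rows are assumed to already be in node-table order.  Sub-tolerance
    asymmetries are symmetrised by averaging; the diagonal is forced to 0.
    """
    sep = _delimiter_for(path)
    with open(path) as fh:
        first = fh.readline()
    has_header = not _is_numeric_row(first, sep)

    if has_header:
        df = pd.read_csv(path, sep=sep)
        file_ids = [str(c) for c in df.columns]
        raw = df.to_numpy(dtype=float)
    else:
        raw = pd.read_csv(path, sep=sep, header=None).to_numpy(dtype=float)
        file_ids = None

    if raw.ndim != 2 or raw.shape[0] != raw.shape[1]:
        raise ShapeError(f"{path}: matrix is not square (shape {raw.shape})")

    if node_table is not None:
        ids = [str(i) for i in node_table["node_id"]]
        if file_ids is not None:
            if set(file_ids) != set(ids):
                raise NodeMismatchError(
                    f"{path}: header node ids do not match the node table"
                )
            order = [file_ids.index(i) for i in ids]
            raw = raw[np.ix_(order, order)]
        elif raw.shape[0] != len(ids):
            raise ShapeError(
                f"{path}: {raw.shape[0]} rows but node table has {len(ids)} nodes"
            )
    else:
        ids = file_ids if file_ids is not None else [
            f"n{i:03d}" for i in range(raw.shape[0])
        ]

    if (raw < 0).any():
        raise NegativeWeightError(f"{path}: negative weights")
    scale = max(np.abs(raw).max(), 1.0)
    if np.abs(raw - raw.T).max() > SYMMETRY_RTOL * scale:
        raise AsymmetryError(f"{path}: asymmetry beyond tolerance")
    w = 0.5 * (raw + raw.T)
    np.fill_diagonal(w, 0.0)

    sid = subject_id if subject_id is not None else _subject_from_path(path)
    return Connectome(sid, w, ids)


def _is_numeric_row(line: str, sep: str) -> bool:
    for tok in line.strip().split(sep):
        try:
            float(tok)
        except ValueError:
            return False
    return True


def _subject_from_path(path: str) -> str:
    return os.path.splitext(os.path.basename(path))[0]


def write_connectome(c: Connectome, path: str, header: bool = True) -> None:
    """Write a connectome as a delimited square matrix (delimiter from extension).

    Round-trips through :func:`read_connectome` reproduce the weights to
    better than 1e-12 relative error (full float precision is written).
    """
    sep = _delimiter_for(path)
    df = pd.DataFrame(c.weights, columns=c.node_ids)
    df.to_csv(path, sep=sep, index=False, header=header, float_format="%.17g")


def read_node_table(path: str) -> pd.DataFrame:
    """Read a node table (node_id, region_name, hemisphere[, partition_label])."""
    sep = _delimiter_for(path)
    df = pd.read_csv(path, sep=sep, dtype={"node_id": str})
    for col in ("node_id", "region_name", "hemisphere"):
        if col not in df.columns:
            raise ValidationError(f"node table missing required column {col!r}")
    if df["node_id"].duplicated().any():
        raise ValidationError("duplicate node_id in node table")
    bad = ~df["hemisphere"].isin(["left", "right", "midline"])
    if bad.any():
        raise ValidationError("hemisphere must be left/right/midline")
    if "partition_label" in df.columns and df["partition_label"].notna().any():
        if df["partition_label"].isna().any():
            raise ValidationError("partition_label must label every node when present")
        bad = ~df["partition_label"].isin(["core", "periphery"])
        if bad.any():
            raise ValidationError("partition_label must be core/periphery")
    return df


def write_node_table(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, sep=_delimiter_for(path), index=False)


def read_cohort(path: str) -> pd.DataFrame:
    """Read the per-subject covariate/outcome table.

    Blank numeric cells stay missing (NaN), never zero; subjects with
    missing values are retained and dropped per-analysis downstream
    (listwise deletion at analysis time).
    """
    sep = _delimiter_for(path)
    df = pd.read_csv(path, sep=sep, dtype={"subject_id": str})
    missing = [c for c in REQUIRED_COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"cohort table missing required columns: {missing}")
    if df["subject_id"].duplicated().any():
        dups = df.loc[df["subject_id"].duplicated(), "subject_id"].tolist()
        raise ValidationError(f"duplicate subject_id(s): {dups}")
    for col in ("internalizing_raw", "externalizing_raw"):
        vals = df[col].dropna()
        if (vals < 0).any() or (vals != np.round(vals)).any():
            raise ValidationError(f"{col} must hold nonnegative integer counts")
    return df


def edge_list(c: Connectome) -> list[Edge]:
    """All positive-weight unordered pairs, sorted by (node_a, node_b)."""
    iu, ju = np.triu_indices(c.n_nodes, k=1)
    pos = c.weights[iu, ju] > 0
    edges = [
        Edge(c.node_ids[i], c.node_ids[j], float(c.weights[i, j]))
        for i, j in zip(iu[pos], ju[pos])
    ]
    return sorted(edges, key=lambda e: (e.node_a, e.node_b))
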