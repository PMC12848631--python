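"""Functional connectivity matrices, edge indexing, and atlas labels.

A subject's resting-state connectome is summarized as a symmetric P x P
matrix of Fisher z-transformed Pearson correlations between node (parcel)
time courses.  Off-diagonal element (i, j) is the edge strength between
parcels i and j; the diagonal is stored as exactly zero and excluded from
all edge-level operations.

Conventions used throughout the package:

* node ids are 1-based (the atlas convention);
* linear edge indices are 0-based, row-major over the strict upper
  triangle, i.e. (1,2), (1,3), ..., (1,P), (2,3), ...
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ConnectomeError",
    "NodeTimeSeries",
    "ConnectivityMatrix",
    "EdgeIndexMap",
    "AtlasLabels",
    "compute_connectivity",
    "vectorize_edges",
    "devectorize_edges",
    "read_matrix",
    "write_matrix",
    "load_atlas_labels",
    "write_atlas_labels",
]

#: |r| at or above this bound is treated as a degenerate (infinite Fisher z) pair.
R_DEGENERATE = 1.0 - 1e-12

#: symmetry tolerance when validating matrices
SYMMETRY_ATOL = 1e-10


class ConnectomeError(ValueError):
    """Invalid connectome input (dimension, symmetry, degeneracy, labels)."""


def _default_node_ids(p: int) -> np.ndarray:
    return np.arange(1, p + 1, dtype=np.int64)


@dataclass
class NodeTimeSeries:
    """Mean time course per node: T timepoints x P nodes."""

    values: np.ndarray
    node_ids: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ConnectomeError("time series must be a 2-D (T x P) array")
        t, p = self.values.shape
        if t < 3:
            raise ConnectomeError(f"need at least 3 timepoints, got {t}")
        if not np.all(np.isfinite(self.values)):
            raise ConnectomeError("time series contains non-finite values")
        if self.node_ids is None:
            self.node_ids = _default_node_ids(p)
        else:
            self.node_ids = np.asarray(self.node_ids, dtype=np.int64)
            if self.node_ids.shape != (p,):
                raise ConnectomeError("node_ids length must equal number of nodes")
            if len(np.unique(self.node_ids)) != p:
                raise ConnectomeError("node_ids must be unique")

    @property
    def n_nodes(self) -> int:
        return self.values.shape[1]

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[0]


@dataclass
class ConnectivityMatrix:
    """Symmetric Fisher-z edge-strength matrix with zero diagonal."""

    values: np.ndarray
    node_ids: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ConnectomeError("connectivity matrix must be square")
        p = self.values.shape[0]
        if not np.all(np.isfinite(self.values)):
            raise ConnectomeError("connectivity matrix contains non-finite values")
        asym = np.abs(self.values - self.values.T).max() if p else 0.0
        if asym > SYMMETRY_ATOL:
            raise ConnectomeError(
                f"matrix is asymmetric (max |M - M.T| = {asym:.3e} > {SYMMETRY_ATOL})"
            )
        if np.any(np.diag(self.values) != 0):
            raise ConnectomeError("diagonal must be exactly zero")
        if self.node_ids is None:
            self.node_ids = _default_node_ids(p)
        else:
            self.node_ids = np.asarray(self.node_ids, dtype=np.int64)
            if self.node_ids.shape != (p,):
                raise ConnectomeError("node_ids length must equal matrix size")

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]


@functools.lru_cache(maxsize=32)
def _upper_triangle(n_nodes: int) -> tuple[np.ndarray, np.ndarray]:
    """Row/col index arrays of the strict upper triangle, row-major."""
    iu = np.triu_indices(n_nodes, k=1)
    return iu[0].astype(np.int64), iu[1].astype(np.int64)


@dataclass(frozen=True)
class EdgeIndexMap:
    """Bijection between node pairs (i < j, 1-based) and linear edge indices.

    Linear indices run 0-based, row-major over the strict upper triangle of
    a P x P matrix, so edge 0 is (1, 2), edge 1 is (1, 3), and edge
    P(P-1)/2 - 1 is (P-1, P).
    """

    n_nodes: int

    def __post_init__(self) -> None:
        if self.n_nodes < 2:
            raise ConnectomeError("need at least 2 nodes")

    @property
    def n_edges(self) -> int:
        return self.n_nodes * (self.n_nodes - 1) // 2

    def to_index(self, i: int, j: int) -> int:
        """Linear edge index for the node pair (i, j), 1-based, i < j."""
        if not (1 <= i < j <= self.n_nodes):
            raise ConnectomeError(
                f"node pair ({i}, {j}) invalid for {self.n_nodes} nodes (need 1 <= i < j <= P)"
            )
        a, b = i - 1, j - 1
        return a * (2 * self.n_nodes - a - 1) // 2 + (b - a - 1)

    def to_pair(self, k: int) -> tuple[int, int]:
        """Node pair (i, j), 1-based, for linear edge index k."""
        if not (0 <= k < self.n_edges):
            raise ConnectomeError(f"edge index {k} out of range [0, {self.n_edges})")
        rows, cols = _upper_triangle(self.n_nodes)
        return int(rows[k]) + 1, int(cols[k]) + 1

    def pairs(self) -> tuple[np.ndarray, np.ndarray]:
        """1-based (i, j) arrays for all edges in linear order."""
        rows, cols = _upper_triangle(self.n_nodes)
        return rows + 1, cols + 1


def compute_connectivity(ts: NodeTimeSeries) -> ConnectivityMatrix:
    """Node-by-node Pearson correlations, Fisher z-transformed.

    Off-diagonal entry (i, j) is atanh(pearson(ts_i, ts_j)); the diagonal is
    set to zero.  A node with zero variance, or a node pair with |r| at the
    atanh singularity (|r| >= 1 - 1e-12), is an error: degenerate inputs are
    surfaced, never silently clamped.
    """
    x = ts.values
    sd = x.std(axis=0)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        ids = ts.node_ids[dead].tolist()
        raise ConnectomeError(f"zero-variance node(s): {ids}")
    r = np.corrcoef(x, rowvar=False)
    r = np.atleast_2d(r)
    off = np.abs(r.copy())
    np.fill_diagonal(off, 0.0)
    bad = np.argwhere(off >= R_DEGENERATE)
    if bad.size:
        a, b = bad[0]
        raise ConnectomeError(
            f"|r| >= {R_DEGENERATE} between nodes "
            f"{int(ts.node_ids[a])} and {int(ts.node_ids[b])}: Fisher z is infinite"
        )
    np.fill_diagonal(r, 0.0)
    z = np.arctanh(r)
    z = (z + z.T) / 2.0  # enforce exact symmetry against rounding
    np.fill_diagonal(z, 0.0)
    return ConnectivityMatrix(z, node_ids=ts.node_ids.copy())


def vectorize_edges(m: ConnectivityMatrix, emap: EdgeIndexMap) -> np.ndarray:
    """Upper-triangle edge values in linear (row-major) order."""
    if emap.n_nodes != m.n_nodes:
        raise ConnectomeError(
            f"edge map for {emap.n_nodes} nodes does not match {m.n_nodes}-node matrix"
        )
    rows, cols = _upper_triangle(m.n_nodes)
    return m.values[rows, cols].copy()


def devectorize_edges(
    v: np.ndarray, emap: EdgeIndexMap, node_ids: np.ndarray | None = None
) -> ConnectivityMatrix:
    """Inverse of :func:`vectorize_edges`: symmetric matrix with zero diagonal."""
    v = np.asarray(v, dtype=float)
    if v.shape != (emap.n_edges,):
        raise ConnectomeError(
            f"edge vector length {v.shape} does not match {emap.n_edges} edges"
        )
    p = emap.n_nodes
    m = np.zeros((p, p), dtype=float)
    rows, cols = _upper_triangle(p)
    m[rows, cols] = v
    m += m.T
    return ConnectivityMatrix(m, node_ids=node_ids)


# ---------------------------------------------------------------------------
# plain-text I/O


def write_matrix(m: ConnectivityMatrix, path: str | Path) -> Path:
    """Write a matrix as tab-delimited text (P rows x P columns, no header)."""
    path = Path(path)
    np.savetxt(path, m.values, delimiter="\t", fmt="%.17g")
    return path

def read_matrix(path: str | Path, node_ids: np.ndarray | None = None) -> ConnectivityMatrix:
    """Read a tab-delimited P x P matrix; validates symmetry and zero diagonal."""
    values = np.loadtxt(path, delimiter="\t", ndmin=2)
    try:
        return ConnectivityMatrix(values, node_ids=node_ids)
    except ConnectomeError as exc:
        raise ConnectomeError(f"{path}: {exc}") from None


ATLAS_REQUIRED = ("node_id", "network_label")
ATLAS_OPTIONAL = ("hemisphere", "x", "y", "z")


@dataclass
class AtlasLabels:
    """Mapping node id -> canonical network label (plus optional coordinates)."""

    table: pd.DataFrame  # indexed by node_id

    def __post_init__(self) -> None:
        if "network_label" not in self.table.columns:
            raise ConnectomeError("atlas table requires a network_label column")
        if self.table.index.has_duplicates:
            dupes = self.table.index[self.table.index.duplicated()].unique().tolist()
            raise ConnectomeError(f"duplicate node id(s) in atlas: {dupes}")

    @property
    def node_ids(self) -> np.ndarray:
        return self.table.index.to_numpy()

    @property
    def networks(self) -> list[str]:
        """Sorted unique network labels."""
        return sorted(self.table["network_label"].unique())

    def network_of(self, node_ids: Sequence[int] | np.ndarray) -> np.ndarray:
        """Network label per node; errors listing any unlabeled node."""
        node_ids = np.asarray(node_ids)
        missing = sorted(set(node_ids.tolist()) - set(self.table.index.tolist()))
        if missing:
            raise ConnectomeError(f"node(s) missing from atlas labels: {missing}")
        return self.table.loc[node_ids, "network_label"].to_numpy()

    def validate_covers(self, node_ids: Sequence[int] | np.ndarray) -> None:
        self.network_of(node_ids)


def load_atlas_labels(path: str | Path) -> AtlasLabels:
    """Load a node_id,network_label CSV (optional hemisphere/x/y/z columns)."""
    df = pd.read_csv(path)
    missing = [c for c in ATLAS_REQUIRED if c not in df.columns]
    if missing:
        raise ConnectomeError(f"{path}: missing required column(s) {missing}")
    unknown = [c for c in df.columns if c not in ATLAS_REQUIRED + ATLAS_OPTIONAL]
    if unknown:
        raise ConnectomeError(f"{path}: unknown column(s) {unknown}")
    df = df.set_index("node_id")
    return AtlasLabels(df)


def write_atlas_labels(labels: AtlasLabels, path: str | Path) -> Path:
    path = Path(path)
    labels.table.reset_index().to_csv(path, index=False)
    return path
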