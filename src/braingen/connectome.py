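"""Binary connectome construction from correlation matrices or ROI series.

Pipeline: Pearson correlation between regional time courses → Fisher r-to-z
variance stabilization → group averaging → strict thresholding at θ to a
binary adjacency.  Thresholding commutes with the (monotone) Fisher
transform, so thresholding on the r scale at θ equals thresholding on the z
scale at arctanh(θ).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .graph_core import BrainGraph

_SYMMETRY_TOL = 1e-10


@dataclass(frozen=True)
class CorrelationMatrix:
    """Square symmetric matrix of inter-regional association values.

    ``value_kind`` distinguishes raw Pearson r ("r") from Fisher-z ("z")
    entries; the diagonal is forced to 0 and ignored downstream.
    """

    node_ids: tuple[int, ...]
    values: np.ndarray
    value_kind: str = "r"

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        n = len(self.node_ids)
        if values.shape != (n, n):
            raise ValueError("matrix shape does not match node count")
        if np.isnan(values).any():
            raise ValueError("correlation matrix contains missing values")
        if not np.allclose(values, values.T, atol=_SYMMETRY_TOL, rtol=0.0):
            raise ValueError("correlation matrix is not symmetric")
        if self.value_kind not in ("r", "z"):
            raise ValueError(f"value_kind must be 'r' or 'z', got {self.value_kind!r}")
        values = values.copy()
        np.fill_diagonal(values, 0.0)
        if self.value_kind == "r":
            off = values[~np.eye(n, dtype=bool)]
            if off.size and (np.abs(off) > 1.0 + 1e-12).any():
                raise ValueError("raw correlation entries must lie in [-1, 1]")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "node_ids", tuple(int(u) for u in self.node_ids))


def pearson_from_timeseries(series: Mapping[int, Sequence[float]]) -> CorrelationMatrix:
    """Pearson correlation between per-node time courses of equal length."""
    node_ids = tuple(series)
    data = [np.asarray(series[u], dtype=float) for u in node_ids]
    lengths = {len(x) for x in data}
    if len(lengths) != 1:
        raise ValueError(f"time series lengths differ: {sorted(lengths)}")
    (t,) = lengths
    if t < 3:
        raise ValueError(f"need at least 3 time points, got {t}")
    for u, x in zip(node_ids, data):
        if np.ptp(x) == 0.0:
            raise ValueError(f"node {u}: constant time series has no defined correlation")
    r = np.corrcoef(np.vstack(data))
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)  # symmetrize away float asymmetry
    return CorrelationMatrix(node_ids, r, value_kind="r")


def fisher_r_to_z(m: CorrelationMatrix) -> CorrelationMatrix:
    """Fisher r-to-z transform z = arctanh(r), elementwise off-diagonal."""
    if m.value_kind != "r":
        raise ValueError("input is already on the z scale")
    off = ~np.eye(len(m.node_ids), dtype=bool)
    if (np.abs(m.values[off]) >= 1.0).any():
        raise ValueError("|r| = 1 found off-diagonal; clip before transforming")
    z = np.arctanh(m.values)
    np.fill_diagonal(z, 0.0)
    return CorrelationMatrix(m.node_ids, z, value_kind="z")


def group_average(matrices: Sequence[CorrelationMatrix]) -> CorrelationMatrix:
    """Elementwise arithmetic mean of matrices over an identical node set."""
    if not matrices:
        raise ValueError("need at least one matrix")
    first = matrices[0]
    for m in matrices[1:]:
        if m.node_ids != first.node_ids:
            raise ValueError("matrices have mismatched node sets")
        if m.value_kind != first.value_kind:
            raise ValueError("cannot average matrices of different value kinds")
    mean = np.mean([m.values for m in matrices], axis=0)
    return CorrelationMatrix(first.node_ids, mean, value_kind=first.value_kind)


def binarize(m: CorrelationMatrix, theta: float) -> BrainGraph:
    """Threshold the matrix into a binary graph: edge iff value > θ (strict)."""
    a = (m.values > theta).astype(np.int8)
    np.fill_diagonal(a, 0)
    a = a & a.T  # symmetric within tolerance by construction
    return BrainGraph.from_adjacency(a, m.node_ids)


# ---------------------------------------------------------------------------
# File formats


def read_correlation_matrix(path: str | Path, value_kind: str = "r") -> CorrelationMatrix:
    """Read a square matrix TSV/CSV with a node-id header row and column."""
    sep = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0)
    node_ids = [int(c) for c in df.columns]
    if [int(r) for r in df.index] != node_ids:
        raise ValueError(f"{path}: row and column node ids differ")
    if df.isna().any().any():
        raise ValueError(f"{path}: missing values are not allowed")
    return CorrelationMatrix(tuple(node_ids), df.to_numpy(dtype=float), value_kind=value_kind)


def write_correlation_matrix(m: CorrelationMatrix, path: str | Path) -> None:
    sep = "," if str(path).endswith(".csv") else "\t"
    pd.DataFrame(m.values, index=m.node_ids, columns=m.node_ids).to_csv(path, sep=sep)


def read_timeseries(path: str | Path) -> dict[int, np.ndarray]:
    """Read a time-series table: one column per node, header row of node ids."""
    sep = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep)
    if df.isna().any().any():
        raise ValueError(f"{path}: missing values are not allowed")
    return {int(c): df[c].to_numpy(dtype=float) for c in df.columns}
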