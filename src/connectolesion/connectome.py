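"""Weighted structural connectomes: I/O, validation, thresholding, binarization.

A connectome here is a symmetric, non-negative, zero-diagonal matrix of
SIFT2-weighted streamline counts over a labelled cortical/subcortical
parcellation.  All graph measures downstream operate on the binary graph
obtained by keeping the strongest fixed proportion of connections
(proportional thresholding, default 20%) and binarizing.
"""
from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

log = logging.getLogger(__name__)

SYMMETRY_TOL = 1e-9
READ_SYMMETRY_TOL = 1e-6

#: Canonical names of the eight right-hemisphere analysis regions.
ROI_NAMES = (
    "superior_frontal",
    "anterior_cingulate",
    "posterior_cingulate",
    "dorsal_anterior_insula",
    "middle_temporal",
    "entorhinal",
    "parahippocampal",
    "fusiform",
)


class ConnectomeError(ValueError):
    """Raised for malformed or inconsistent connectivity input."""


@dataclass(frozen=True)
class WeightedConnectome:
    """Symmetric non-negative weighted connectivity matrix with region labels."""

    labels: tuple[str, ...]
    weights: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "labels", tuple(self.labels))
        n = len(self.labels)
        if w.ndim != 2 or w.shape != (n, n):
            raise ConnectomeError(
                f"weight matrix shape {w.shape} does not match {n} labels"
            )
        if n < 3:
            raise ConnectomeError(f"need at least 3 regions, got {n}")
        if len(set(self.labels)) != n:
            raise ConnectomeError("duplicate region labels")
        if np.any(w < 0):
            raise ConnectomeError("negative connection weight")
        if np.max(np.abs(w - w.T), initial=0.0) > SYMMETRY_TOL:
            raise ConnectomeError("weight matrix is not symmetric")
        if np.any(np.diag(w) != 0):
            raise ConnectomeError("diagonal must be exactly zero")

    @property
    def n(self) -> int:
        return len(self.labels)


@dataclass(frozen=True)
class BinaryGraph:
    """Thresholded/binarized undirected adjacency with edge density."""

    labels: tuple[str, ...]
    adjacency: np.ndarray
    density: float = field(default=float("nan"))

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency)
        if not np.isin(a, (0, 1)).all():
            raise ConnectomeError("adjacency entries must be 0 or 1")
        a = a.astype(np.int8)
        object.__setattr__(self, "adjacency", a)
        object.__setattr__(self, "labels", tuple(self.labels))
        n = len(self.labels)
        if a.shape != (n, n):
            raise ConnectomeError("adjacency shape does not match labels")
        if np.any(a != a.T):
            raise ConnectomeError("adjacency is not symmetric")
        if np.any(np.diag(a) != 0):
            raise ConnectomeError("adjacency diagonal must be zero")
        dens = int(np.triu(a, 1).sum()) / (n * (n - 1) / 2)
        if math.isnan(self.density):
            object.__setattr__(self, "density", dens)
        elif abs(self.density - dens) > 1e-12:
            raise ConnectomeError("stated density inconsistent with adjacency")

    @property
    def n(self) -> int:
        return len(self.labels)


@dataclass(frozen=True)
class RegionSet:
    """The 8 analysis ROIs resolved to node indices (right hemisphere)."""

    roi_names: tuple[str, ...]
    node_indices: dict[str, int]
    hemisphere: str = "right"

    def __post_init__(self) -> None:
        if len(self.roi_names) != 8:
            raise ConnectomeError("a RegionSet holds exactly 8 ROIs")
        idx = [self.node_indices[r] for r in self.roi_names]
        if len(set(idx)) != len(idx):
            raise ConnectomeError("duplicate node indices in RegionSet")


def read_connectome(path: str | Path, expected_n: int | None = None) -> WeightedConnectome:
    """Read a TSV connectome (header row of labels, then an n x n matrix).

    Sub-tolerance asymmetries (tractography export artifacts) are averaged
    away; anything larger is an error, as are negative weights, duplicate
    labels and a size mismatch with ``expected_n``.
    """
    path = Path(path)
    with open(path, newline="", encoding="utf-8") as fh:
        rows = list(csv.reader(fh, delimiter="\t"))
    if not rows:
        raise ConnectomeError(f"{path}: empty file")
    labels = [c.strip() for c in rows[0]]
    n = len(labels)
    data = rows[1:]
    if len(data) != n or any(len(r) != n for r in data):
        raise ConnectomeError(f"{path}: not a square {n}x{n} matrix")
    if expected_n is not None and n != expected_n:
        raise ConnectomeError(f"{path}: expected {expected_n} regions, found {n}")
    try:
        w = np.array(data, dtype=float)
    except ValueError as exc:
        raise ConnectomeError(f"{path}: non-numeric entry ({exc})") from exc
    asym = float(np.max(np.abs(w - w.T), initial=0.0))
    if asym >= READ_SYMMETRY_TOL:
        raise ConnectomeError(f"{path}: asymmetry {asym:g} exceeds tolerance")
    if asym > 0:
        w = (w + w.T) / 2
    np.fill_diagonal(w, 0.0)
    return WeightedConnectome(labels=tuple(labels), weights=w)


def write_connectome(conn: WeightedConnectome, path: str | Path) -> None:
    """Write a connectome as TSV; full float precision so round-trips are exact."""
    path = Path(path)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        fh.write("\t".join(conn.labels) + "\n")
        for row in conn.weights:
            fh.write("\t".join(f"{v:.17g}" for v in row) + "\n")


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def threshold_proportional(
    conn: WeightedConnectome,
    proportion: float = 0.20,
    of_nonzero: bool = False,
) -> WeightedConnectome:
    """Keep the ``proportion`` strongest connections, zero the rest.

    The retained count is k = round(proportion * E) where E is the number of
    possible edges n(n-1)/2 (or, with ``of_nonzero``, the number of positive
    edges).  Ties at the cutoff are broken by row-major edge order so the
    result is deterministic.  Rounding is half-away-from-zero.
    """
    if not 0 < proportion <= 1:
        raise ValueError(f"proportion must be in (0, 1], got {proportion}")
    w = conn.weights
    n = conn.n
    iu, ju = np.triu_indices(n, 1)
    vals = w[iu, ju]
    pos = vals > 0
    n_pos = int(pos.sum())
    if n_pos == 0:
        raise ConnectomeError("all-zero matrix cannot be thresholded")
    total = n_pos if of_nonzero else len(vals)
    k = _round_half_away(proportion * total)
    if n_pos < k:
        log.warning(
            "only %d positive weights for requested k=%d; retaining all", n_pos, k
        )
        k = n_pos
    # stable sort on descending weight; row-major order breaks ties
    order = np.argsort(-vals, kind="stable")[:k]
    out = np.zeros_like(w)
    out[iu[order], ju[order]] = vals[order]
    out = out + out.T
    return WeightedConnectome(labels=conn.labels, weights=out)


def binarize(conn: WeightedConnectome) -> BinaryGraph:
    """Binary graph with an edge wherever the weight is positive."""
    adj = (conn.weights > 0).astype(np.int8)
    return BinaryGraph(labels=conn.labels, adjacency=adj)


def resolve_rois(
    labels: Sequence[str], roi_table: Mapping[str, str] | None = None
) -> RegionSet:
    """Map the 8 ROI names to node indices through their atlas labels."""
    if roi_table is None:
        roi_table = default_roi_table()
    indices: dict[str, int] = {}
    labels = list(labels)
    for roi, atlas_label in roi_table.items():
        hits = [i for i, lab in enumerate(labels) if lab == atlas_label]
        if not hits:
            raise ConnectomeError(f"atlas label {atlas_label!r} (ROI {roi}) not found")
        if len(hits) > 1:
            raise ConnectomeError(f"atlas label {atlas_label!r} is ambiguous")
        indices[roi] = hits[0]
    return RegionSet(roi_names=tuple(roi_table), node_indices=indices)


def default_roi_table() -> dict[str, str]:
    """The packaged ROI -> atlas-label table (synthetic mnemonic labels)."""
    with resources.files("connectolesion.data").joinpath("roi_table.csv").open(
        encoding="utf-8"
    ) as fh:
        reader = csv.reader(fh)
        header = next(reader)
        assert header == ["roi_name", "atlas_label"]
        return {row[0]: row[1] for row in reader}


def load_roi_table(path: str | Path) -> dict[str, str]:
    """Read a two-column (roi_name, atlas_label) CSV."""
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        rows = [r for r in reader if r]
    if rows and rows[0][:2] == ["roi_name", "atlas_label"]:
        rows = rows[1:]
    table = {r[0]: r[1] for r in rows}
    if len(table) != 8:
        raise ConnectomeError(f"ROI table must have 8 rows, found {len(table)}")
    return table


def default_node_labels(n_nodes: int = 225) -> tuple[str, ...]:
    """Deterministic label list of length ``n_nodes`` containing the 8 ROI labels.

    ROI labels are placed one per eighth of the parcellation so that, under
    the modular synthetic generator, each ROI sits in a distinct module.
    Remaining nodes get generic right/left region names.
    """
    if n_nodes < 16:
        raise ValueError("parcellation too small to host the 8 ROIs")
    table = default_roi_table()
    labels = [f"region_{i:03d}" for i in range(n_nodes)]
    for r, roi in enumerate(table):
        pos = int((r + 0.5) * n_nodes / 8)
        labels[pos] = table[roi]
    return tuple(labels)
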