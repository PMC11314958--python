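"""Virtual single-node failure and the resilience statistic ΔGE.

ΔGE = GE_lesion − GE: the change in global efficiency after computationally
removing one region from the (thresholded, binarized) network.  Values near
zero mean the network tolerates that region's failure; strongly negative
values mean the network relied on it.
"""
from __future__ import annotations

from typing import Literal

import numpy as np

from .connectome import BinaryGraph, RegionSet
from .metrics import global_efficiency

LesionMode = Literal["delete", "zero"]


def lesion_node(g: BinaryGraph, node: int) -> BinaryGraph:
    """Remove one node: delete its row/column and label; input is untouched."""
    if not 0 <= node < g.n:
        raise IndexError(f"node {node} out of range for n={g.n}")
    keep = np.arange(g.n) != node
    adj = g.adjacency[np.ix_(keep, keep)]
    labels = tuple(lab for i, lab in enumerate(g.labels) if keep[i])
    return BinaryGraph(labels=labels, adjacency=adj)


def _lesion_zero(g: BinaryGraph, node: int) -> BinaryGraph:
    """Mask a node by zeroing its row/column, keeping n nodes (sensitivity mode)."""
    if not 0 <= node < g.n:
        raise IndexError(f"node {node} out of range for n={g.n}")
    adj = g.adjacency.copy()
    adj[node, :] = 0
    adj[:, node] = 0
    return BinaryGraph(labels=g.labels, adjacency=adj)


def delta_global_efficiency(
    g: BinaryGraph, node: int, mode: LesionMode = "delete"
) -> float:
    """ΔGE = GE(lesioned) − GE(intact) for a single-node failure.

    ``delete`` (default) averages the lesioned efficiency over the remaining
    (n−1)(n−2) ordered pairs; ``zero`` keeps n nodes and masks the region's
    connections, which forces 2(n−1) permanently unreachable pairs.
    """
    if g.n < 3:
        raise ValueError("need n >= 3 to lesion a node")
    lesioned = lesion_node(g, node) if mode == "delete" else _lesion_zero(g, node)
    return global_efficiency(lesioned) - global_efficiency(g)


def resilience_profile(
    g: BinaryGraph, rois: RegionSet, mode: LesionMode = "delete"
) -> dict[str, float]:
    """ΔGE per ROI; each lesion is applied independently to the intact graph."""
    return {
        roi: delta_global_efficiency(g, rois.node_indices[roi], mode=mode)
        for roi in rois.roi_names
    }
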