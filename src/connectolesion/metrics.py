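"""Binary undirected graph measures, implemented from scratch.

Global efficiency (integration), nodal/mean clustering coefficient
(segregation), and eigenvector centrality.  All operate on a
:class:`~connectolesion.connectome.BinaryGraph`; weighted variants are out
of scope because the analysis binarizes first.
"""
from __future__ import annotations

import logging

import numpy as np

from .connectome import BinaryGraph

log = logging.getLogger(__name__)

_DEGENERACY_TOL = 1e-10


def shortest_path_lengths(g: BinaryGraph) -> np.ndarray:
    """All-pairs hop counts by breadth-first search from every node.

    Returns an n x n float matrix; unreachable pairs are ``inf``.  The BFS
    frontiers of all sources are expanded simultaneously through boolean
    matrix products.
    """
    n = g.n
    a = g.adjacency.astype(np.float32)
    dist = np.full((n, n), np.inf)
    np.fill_diagonal(dist, 0.0)
    reached = np.eye(n, dtype=bool)
    frontier = np.eye(n, dtype=bool)
    d = 0
    while frontier.any():
        d += 1
        frontier = ((frontier.astype(np.float32) @ a) > 0) & ~reached
        dist[frontier] = d
        reached |= frontier
    return dist


def global_efficiency(g: BinaryGraph) -> float:
    """Mean inverse shortest-path length over ordered node pairs, in [0, 1].

    1/inf counts as 0, so disconnected graphs get finite efficiency.
    """
    n = g.n
    if n < 2:
        raise ValueError("global efficiency needs at least 2 nodes")
    dist = shortest_path_lengths(g)
    with np.errstate(divide="ignore"):
        inv = 1.0 / dist
    np.fill_diagonal(inv, 0.0)
    inv[np.isinf(dist)] = 0.0
    return float(inv.sum() / (n * (n - 1)))


def nodal_clustering(g: BinaryGraph) -> np.ndarray:
    """Fraction of closed triangles around each node.

    cc_i = 2 t_i / (k_i (k_i - 1)); nodes of degree < 2 get 0 and are kept
    in the mean (matching standard toolbox conventions).
    """
    a = g.adjacency.astype(np.float64)
    k = a.sum(axis=1)
    triangles = np.einsum("ij,jk,ki->i", a, a, a) / 2.0
    denom = k * (k - 1)
    cc = np.zeros(g.n)
    ok = denom > 0
    cc[ok] = 2.0 * triangles[ok] / denom[ok]
    return cc


def mean_clustering(g: BinaryGraph) -> float:
    """Unweighted mean of the nodal clustering coefficients over all nodes."""
    return float(nodal_clustering(g).mean())


def eigenvector_centrality(g: BinaryGraph) -> np.ndarray:
    """Non-negative leading eigenvector of the adjacency, Euclidean norm 1.

    Dense symmetric eigendecomposition; the sign is fixed so the
    largest-magnitude entry is positive.  On disconnected graphs the vector
    localizes on the component with the largest spectral radius; if that
    eigenvalue is degenerate (e.g. isomorphic twin components) the component
    containing the smallest node index wins, deterministically.
    """
    a = g.adjacency.astype(np.float64)
    if not a.any():
        raise ValueError("eigenvector centrality is undefined on an edgeless graph")
    evals, evecs = np.linalg.eigh(a)
    lam = evals[-1]
    degenerate = np.sum(evals > lam - _DEGENERACY_TOL) > 1
    if degenerate:
        log.warning("degenerate leading eigenvalue; using smallest-index component")
        v = _degenerate_leading_vector(g, lam)
    else:
        v = evecs[:, -1]
    i = int(np.argmax(np.abs(v)))
    if v[i] < 0:
        v = -v
    v = np.clip(v, 0.0, None)  # Perron vector; tiny negatives are roundoff
    return v / np.linalg.norm(v)


def _components(g: BinaryGraph) -> list[np.ndarray]:
    dist = shortest_path_lengths(g)
    seen = np.zeros(g.n, dtype=bool)
    comps = []
    for i in range(g.n):
        if not seen[i]:
            members = np.where(np.isfinite(dist[i]))[0]
            seen[members] = True
            comps.append(members)
    return comps


def _degenerate_leading_vector(g: BinaryGraph, lam: float) -> np.ndarray:
    """Perron vector of the smallest-index component attaining the top eigenvalue."""
    a = g.adjacency.astype(np.float64)
    for members in _components(g):  # ordered by smallest member index
        sub = a[np.ix_(members, members)]
        sub_evals, sub_evecs = np.linalg.eigh(sub)
        if sub_evals[-1] > lam - _DEGENERACY_TOL:
            v = np.zeros(g.n)
            v[members] = np.abs(sub_evecs[:, -1])
            return v
    raise AssertionError("no component attains the leading eigenvalue")
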