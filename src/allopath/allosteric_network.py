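"""Dynamical-network construction and suboptimal communication paths.

Residue Calpha atoms are the nodes.  An edge joins two residues when they
stay within a distance cutoff (default 4.5 A) in at least a fraction
(default 0.75) of the frames, and its length is

    w_ij = -log |C_ij|

so strongly correlated contacts are short.  Optimal paths come from
Floyd-Warshall; the top-k suboptimal paths between a source and a sink are
enumerated with Yen's k-shortest-simple-paths algorithm, with equal-length
paths ordered lexicographically by node sequence for determinism.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import networkx as nx
import numpy as np
from scipy.spatial.distance import cdist

from .dynamics import CorrelationMatrix
from .ensemble_io import Ensemble, residue_groups
from .errors import SpecificationError

__all__ = [
    "ContactMap",
    "DynamicalNetwork",
    "Path",
    "PathSet",
    "PathHistogram",
    "contact_fractions",
    "build_network",
    "optimal_paths",
    "suboptimal_paths",
    "path_histogram",
]

#: Relative tolerance treating two path lengths as tied.
_LENGTH_EPS = 1e-9


@dataclass
class ContactMap:
    """Fraction of frames each residue pair spends within the cutoff."""

    labels: list[tuple[str, int]]
    F: np.ndarray
    cutoff: float = 4.5


@dataclass
class DynamicalNetwork:
    graph: nx.Graph  # nodes: (chain, resid); edge attrs: weight, correlation
    cutoff: float = 4.5
    fraction_threshold: float = 0.75

    @property
    def nodes(self) -> list:
        return list(self.graph.nodes)


@dataclass
class Path:
    nodes: tuple
    length: float


@dataclass
class PathSet:
    source: object
    sink: object
    paths: list[Path]
    k_requested: int
    reachable: bool = True

    @property
    def lengths(self) -> np.ndarray:
        return np.array([p.length for p in self.paths])

    @property
    def optimal(self) -> Path:
        return self.paths[0]


@dataclass
class PathHistogram:
    bin_edges: np.ndarray
    counts: np.ndarray


# ---------------------------------------------------------------------------


def contact_fractions(
    traj: Ensemble,
    cutoff: float = 4.5,
    mode: str = "heavy",
    residues: Sequence[tuple[str, int]] | None = None,
) -> ContactMap:
    """Per-pair fraction of frames with inter-residue distance < cutoff.

    ``mode='heavy'`` uses the closest heavy-atom distance between the two
    residues (the NetworkView convention); ``mode='ca'`` uses the CA-CA
    distance.  Diagonal is 1 by convention.
    """
    if mode not in ("heavy", "ca"):
        raise SpecificationError(f"unknown contact mode {mode!r}")
    groups = residue_groups(traj)
    if residues is not None:
        groups = {r: groups[r] for r in residues}
    labels = list(groups)
    n = len(labels)
    atoms0 = traj.models[0].atoms
    if mode == "ca":
        sel = []
        for r in labels:
            ca = [i for i in groups[r] if atoms0[int(i)].name == "CA"]
            if len(ca) != 1:
                raise SpecificationError(f"residue {r} has {len(ca)} CA atoms")
            sel.append(ca[0])
        idx_groups = [np.array([i]) for i in sel]
    else:
        idx_groups = [groups[r][[atoms0[int(i)].element != "H" for i in groups[r]]]
                      for r in labels]
    coords = traj.coords()
    counts = np.zeros((n, n))
    single = all(len(g) == 1 for g in idx_groups)
    if single:
        flat = np.array([g[0] for g in idx_groups])
        for t in range(traj.n_models):
            d = cdist(coords[t, flat], coords[t, flat])
            counts += d < cutoff
    else:
        for t in range(traj.n_models):
            for a in range(n):
                for b in range(a + 1, n):
                    d = cdist(
                        coords[t, idx_groups[a]], coords[t, idx_groups[b]]
                    ).min()
                    if d < cutoff:
                        counts[a, b] += 1
                        counts[b, a] += 1
    F = counts / traj.n_models
    np.fill_diagonal(F, 1.0)
    return ContactMap(labels=labels, F=F, cutoff=cutoff)


def build_network(
    cmap: ContactMap,
    corr: CorrelationMatrix,
    fraction_threshold: float = 0.75,
    exclude_sequence_neighbors: bool = True,
) -> DynamicalNetwork:
    """Admit edges for persistent contacts, weighted by -log |C_ij|.

    Sequence-neighbour (i, i+-1 on one chain) edges are excluded by default
    so that communication paths cannot trivially run along the backbone.
    Contacts with C_ij = 0 yield no edge (infinite length) with a warning.
    """
    if cmap.labels != corr.labels:
        raise SpecificationError("contact map and correlation matrix labels differ")
    labels = cmap.labels
    g = nx.Graph()
    g.add_nodes_from(labels)
    n = len(labels)
    dropped = 0
    for i in range(n):
        for j in range(i + 1, n):
            if cmap.F[i, j] < fraction_threshold:
                continue
            if (
                exclude_sequence_neighbors
                and labels[i][0] == labels[j][0]
                and abs(labels[i][1] - labels[j][1]) == 1
            ):
                continue
            c = abs(corr.C[i, j])
            if c <= 0.0:
                dropped += 1
                continue
            g.add_edge(labels[i], labels[j], weight=float(-np.log(c)), correlation=c)
    if dropped:
        warnings.warn(
            f"{dropped} persistent contacts had zero correlation; no edge added",
            stacklevel=2,
        )
    return DynamicalNetwork(
        graph=g, cutoff=cmap.cutoff, fraction_threshold=fraction_threshold
    )


def optimal_paths(net: DynamicalNetwork) -> tuple[dict, dict]:
    """All-pairs shortest path lengths and predecessors (Floyd-Warshall).

    Returns (distance, predecessor) nested dicts keyed by node; pairs left
    out of the distance dict are unreachable.
    """
    pred, dist = nx.floyd_warshall_predecessor_and_distance(net.graph, weight="weight")
    return dist, pred


def _path_length(g: nx.Graph, nodes: Sequence) -> float:
    return float(sum(g[u][v]["weight"] for u, v in zip(nodes, nodes[1:])))


def suboptimal_paths(
    net: DynamicalNetwork, source, sink, k: int = 1000
) -> PathSet:
    """The k distinct simple paths of smallest total length, ascending.

    Fewer than k paths are returned if the graph admits fewer.  Equal
    lengths are ordered lexicographically by node sequence; the first path
    is always the optimal one.
    """
    g = net.graph
    for node in (source, sink):
        if node not in g:
            raise SpecificationError(f"node {node!r} not in network")
    if not nx.has_path(g, source, sink):
        return PathSet(source=source, sink=sink, paths=[], k_requested=k,
                       reachable=False)
    collected: list[Path] = []
    kth_len = np.inf
    gen = nx.shortest_simple_paths(g, source, sink, weight="weight")
    for nodes in gen:
        length = _path_length(g, nodes)
        if len(collected) >= k and length > kth_len * (1 + _LENGTH_EPS) + _LENGTH_EPS:
            break
        collected.append(Path(nodes=tuple(nodes), length=length))
        if len(collected) == k:
            kth_len = length
    # lexicographic tie order on (length rounded past float jitter, nodes)
    collected.sort(key=lambda p: (round(p.length, 10), p.nodes))
    return PathSet(source=source, sink=sink, paths=collected[:k], k_requested=k)


def path_histogram(
    ps: PathSet, bins: int | Sequence[float] = 20,
) -> PathHistogram:
    """Histogram of path lengths; counts sum to the number of paths."""
    if not ps.paths:
        raise SpecificationError("cannot histogram an empty path set")
    lengths = ps.lengths
    if np.ndim(bins) > 0:
        edges = np.asarray(bins, float)
        if lengths.min() < edges[0] or lengths.max() > edges[-1]:
            raise SpecificationError("bin edges do not cover all path lengths")
        counts, edges = np.histogram(lengths, bins=edges)
    else:
        counts, edges = np.histogram(lengths, bins=int(bins))
    return PathHistogram(bin_edges=edges, counts=counts)
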