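"""Weighted homology graph and Louvain modularity clustering.

Protein families are recovered as communities of the undirected homology
graph (vertices: sequences; edges: accepted alignments weighted by
alignment length).  Communities are found with the two-phase Louvain
heuristic, greedily optimizing Newman's weighted modularity

    Q = (1 / 2m) * sum_ij [A_ij - k_i k_j / 2m] * delta(c_i, c_j)

where m is the total edge weight and k the weighted degree.  The heuristic
is order-sensitive, so the vertex visit order is a seeded random permutation
per pass and ties between equally improving communities break toward the
lowest community id — runs are fully reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .model import ProteomeSet


class GraphError(ValueError):
    pass


@dataclass
class HomologyGraph:
    """Undirected graph with positive edge weights; no self-loops."""

    vertices: list[str] = field(default_factory=list)
    _adj: dict[str, dict[str, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.vertices)) != len(self.vertices):
            raise GraphError("duplicate vertices")
        for v in self.vertices:
            self._adj.setdefault(v, {})

    def add_vertex(self, v: str) -> None:
        if v not in self._adj:
            self.vertices.append(v)
            self._adj[v] = {}

    def add_edge(self, u: str, v: str, weight: float) -> None:
        if u == v:
            raise GraphError(f"self-loop on {u!r}")
        if weight <= 0:
            raise GraphError("edge weights must be positive")
        if u not in self._adj or v not in self._adj:
            raise GraphError("edge endpoint not a vertex")
        if v in self._adj[u]:
            raise GraphError(f"duplicate edge {u!r}-{v!r}")
        self._adj[u][v] = weight
        self._adj[v][u] = weight

    def neighbors(self, v: str) -> dict[str, float]:
        return self._adj[v]

    def degree(self, v: str) -> float:
        return sum(self._adj[v].values())

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_edges(self) -> int:
        return sum(len(nb) for nb in self._adj.values()) // 2

    def total_weight(self) -> float:
        """Sum of edge weights (each edge counted once)."""
        return sum(w for v in self._adj for w in self._adj[v].values()) / 2.0

    def edges(self) -> list[tuple[str, str, float]]:
        out = []
        for u in sorted(self._adj):
            for v, w in sorted(self._adj[u].items()):
                if u < v:
                    out.append((u, v, w))
        return out


@dataclass(frozen=True)
class CensusCounts:
    """Counts of the three cluster classes."""

    singleton: int
    single_organism_multi: int
    multi_organism: int

    @property
    def total(self) -> int:
        return self.singleton + self.single_organism_multi + self.multi_organism

    @property
    def non_singleton(self) -> int:
        return self.single_organism_multi + self.multi_organism

    @classmethod
    def from_totals(cls, total_clusters: int, singletons: int,
                    single_organism: int) -> "CensusCounts":
        """Recover the multi-organism count from published census totals."""
        multi = total_clusters - singletons - single_organism
        if multi < 0:
            raise ValueError("inconsistent census totals")
        return cls(singleton=singletons, single_organism_multi=single_organism,
                   multi_organism=multi)


@dataclass
class Clustering:
    """A partition of all sequences plus its modularity and census."""

    assignment: dict[str, int]
    modularity: float
    census: CensusCounts | None = None

    def clusters(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {}
        for sid in sorted(self.assignment):
            out.setdefault(self.assignment[sid], []).append(sid)
        return out

    @property
    def n_clusters(self) -> int:
        return len(set(self.assignment.values()))


def modularity(graph: HomologyGraph, assignment: Mapping[str, int]) -> float:
    """Newman weighted modularity of a partition; 0 for an edgeless graph."""
    missing = [v for v in graph.vertices if v not in assignment]
    if missing:
        raise GraphError(f"vertices missing from assignment: {missing[:5]}")
    m = graph.total_weight()
    if m == 0:
        return 0.0
    q = 0.0
    deg_by_com: dict[int, float] = {}
    for v in graph.vertices:
        deg_by_com[assignment[v]] = deg_by_com.get(assignment[v], 0.0) + graph.degree(v)
    intra = 0.0
    for u, v, w in graph.edges():
        if assignment[u] == assignment[v]:
            intra += w
    q = intra / m - sum(d * d for d in deg_by_com.values()) / (4.0 * m * m)
    return q


def _one_level(adj: list[dict[int, float]], self_w: list[float], m: float,
               rng: np.random.Generator, min_gain: float) -> tuple[list[int], bool]:
    """Louvain local-moving phase on an integer-indexed graph.

    ``adj[i]`` maps neighbor -> weight (no self entries); ``self_w[i]`` is
    the self-loop weight accumulated by aggregation.  Returns the node ->
    community map and whether any move improved modularity.
    """
    n = len(adj)
    node2com = list(range(n))
    k = [sum(adj[i].values()) + 2.0 * self_w[i] for i in range(n)]
    sigma_tot = k.copy()
    improved_any = False
    while True:
        moved = False
        for i in rng.permutation(n):
            com_i = node2com[i]
            # weights to neighboring communities
            w2c: dict[int, float] = {}
            for j, w in adj[i].items():
                w2c[node2com[j]] = w2c.get(node2com[j], 0.0) + w
            sigma_tot[com_i] -= k[i]
            base = w2c.get(com_i, 0.0) - sigma_tot[com_i] * k[i] / (2.0 * m)
            best_com, best_gain = com_i, 0.0
            for c in sorted(w2c):
                if c == com_i:
                    continue
                gain = (w2c[c] - sigma_tot[c] * k[i] / (2.0 * m)) - base
                if gain > best_gain + 1e-15 or (
                        abs(gain - best_gain) <= 1e-15 and best_gain > 0.0
                        and c < best_com):
                    best_com, best_gain = c, gain
            if best_com != com_i and best_gain / m >= min_gain:
                node2com[i] = best_com
                sigma_tot[best_com] += k[i]
                moved = True
                improved_any = True
            else:
                sigma_tot[com_i] += k[i]
        if not moved:
            break
    return node2com, improved_any


def _aggregate(adj: list[dict[int, float]], self_w: list[float],
               node2com: list[int]) -> tuple[list[dict[int, float]], list[float], list[int]]:
    coms = sorted(set(node2com))
    remap = {c: i for i, c in enumerate(coms)}
    n2 = len(coms)
    new_adj: list[dict[int, float]] = [{} for _ in range(n2)]
    new_self = [0.0] * n2
    for i, nb in enumerate(adj):
        ci = remap[node2com[i]]
        new_self[ci] += self_w[i]
        for j, w in nb.items():
            cj = remap[node2com[j]]
            if ci == cj:
                if i < j:
                    new_self[ci] += w
            else:
                new_adj[ci][cj] = new_adj[ci].get(cj, 0.0) + w
    return new_adj, new_self, [remap[c] for c in node2com]


def _louvain_once(adj0: list[dict[int, float]], m: float, n: int,
                  seed: int, min_gain: float) -> list[int]:
    """One full Louvain run; returns fine-grained membership per node index."""
    adj = [dict(a) for a in adj0]
    self_w = [0.0] * n
    rng = np.random.default_rng(seed)
    membership = list(range(n))
    while True:
        node2com, improved = _one_level(adj, self_w, m, rng, min_gain)
        if not improved:
            break
        adj, self_w, compact = _aggregate(adj, self_w, node2com)
        membership = [compact[membership[i]] for i in range(n)]
    return membership


def louvain(graph: HomologyGraph, seed: int = 0, min_gain: float = 1e-9,
            proteome: ProteomeSet | None = None,
            n_restarts: int = 5) -> Clustering:
    """Two-phase Louvain clustering of the homology graph.

    The greedy local-moving phase depends on vertex visit order and can
    settle in a local optimum, so the whole procedure is restarted
    ``n_restarts`` times with distinct seeded visit orders and the
    highest-modularity partition is kept.  Isolated vertices become
    singleton clusters.  Cluster ids are relabeled 0..C-1 by first
    appearance in sorted vertex order, so identical inputs give identical
    cluster files.  If ``proteome`` is given, the census is attached.
    """
    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")
    verts = sorted(graph.vertices)
    idx = {v: i for i, v in enumerate(verts)}
    adj0: list[dict[int, float]] = [
        {idx[u]: w for u, w in graph.neighbors(v).items()} for v in verts
    ]
    m = graph.total_weight()

    best_membership = list(range(len(verts)))
    if m > 0:
        seeds = np.random.default_rng(seed).integers(0, 2**31, size=n_restarts)
        best_q = None
        for s in seeds:
            membership = _louvain_once(adj0, m, len(verts), int(s), min_gain)
            q = _membership_modularity(adj0, membership, m)
            if best_q is None or q > best_q + 1e-12:
                best_q, best_membership = q, membership

    # deterministic relabel by first appearance over sorted vertices
    relabel: dict[int, int] = {}
    assignment: dict[str, int] = {}
    for v in verts:
        c = best_membership[idx[v]]
        if c not in relabel:
            relabel[c] = len(relabel)
        assignment[v] = relabel[c]
    q = modularity(graph, assignment)
    census = classify_clusters_from_assignment(assignment, proteome) if proteome else None
    return Clustering(assignment=assignment, modularity=q, census=census)


def _membership_modularity(adj: list[dict[int, float]],
                           membership: list[int], m: float) -> float:
    """Newman weighted modularity for an index-based membership list."""
    in_w: dict[int, float] = {}
    tot_w: dict[int, float] = {}
    for i, nbrs in enumerate(adj):
        c = membership[i]
        for j, w in nbrs.items():
            tot_w[c] = tot_w.get(c, 0.0) + w
            if membership[j] == c:
                in_w[c] = in_w.get(c, 0.0) + w
    q = 0.0
    for c, tw in tot_w.items():
        q += in_w.get(c, 0.0) / (2.0 * m) - (tw / (2.0 * m)) ** 2
    return q


def classify_clusters_from_assignment(assignment: Mapping[str, int],
                                      proteome: ProteomeSet) -> CensusCounts:
    """Label each cluster singleton / single-organism / multi-organism."""
    orgs_by_cluster: dict[int, set[str]] = {}
    size_by_cluster: dict[int, int] = {}
    for sid, cid in assignment.items():
        size_by_cluster[cid] = size_by_cluster.get(cid, 0) + 1
        orgs_by_cluster.setdefault(cid, set()).add(proteome.records[sid].organism_id)
    singleton = sum(1 for c, s in size_by_cluster.items() if s == 1)
    single_org = sum(1 for c, s in size_by_cluster.items()
                     if s >= 2 and len(orgs_by_cluster[c]) == 1)
    multi = sum(1 for c, s in size_by_cluster.items()
                if s >= 2 and len(orgs_by_cluster[c]) > 1)
    return CensusCounts(singleton=singleton, single_organism_multi=single_org,
                        multi_organism=multi)


def classify_clusters(clustering: Clustering, proteome: ProteomeSet) -> CensusCounts:
    census = classify_clusters_from_assignment(clustering.assignment, proteome)
    clustering.census = census
    return census
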