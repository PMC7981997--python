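"""MCODE molecular-complex detection.

The Bader-Hogue algorithm in its three stages:

1. *Vertex weighting* — each vertex is scored by the density of the
   highest k-core of its closed neighborhood times that core's k.
   Vertices below the degree cutoff are zero-weighted: they cannot seed a
   complex but may still be absorbed into one.
2. *Complex prediction* — complexes grow outward from the highest-weight
   unvisited seed, including neighbors whose weight is within
   ``node_score_cutoff`` (as a fraction) of the seed weight.
3. *Post-processing* — each complex is reduced to the k-core (default
   2-core) of its induced subgraph ("haircut"); complexes without such a
   core are discarded.  "Fluff" (adding dense neighbors, which may create
   overlapping complexes) is off by default.

The complex quality score is density x node count, i.e.
``n * 2e / (n(n-1))``, so a clique of n nodes scores exactly n.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd


@dataclass(frozen=True)
class VertexWeight:
    node: str
    k_max: int
    weight: float


@dataclass(frozen=True)
class Cluster:
    """An MCODE complex: member set, seed, size, internal edges, density, score."""

    members: frozenset
    seed: str
    n: int
    e: int
    density: float
    score: float


def k_core(graph: nx.Graph, k: int) -> nx.Graph:
    """Maximal subgraph of minimum degree >= k, by iterative pruning.

    Returns an empty graph when no such subgraph exists.
    """
    sub = graph.copy()
    sub.remove_edges_from(nx.selfloop_edges(sub))
    while True:
        low = [v for v, d in sub.degree() if d < k]
        if not low:
            return sub
        sub.remove_nodes_from(low)


def _density(n: int, e: int) -> float:
    if n < 2:
        return 0.0
    return 2.0 * e / (n * (n - 1))


def _core_weight(sub: nx.Graph) -> tuple[int, float]:
    """(k_max, k_max * density of the k_max-core) of a graph."""
    k, core = 0, sub
    while True:
        nxt = k_core(sub, k + 1)
        if nxt.number_of_nodes() == 0:
            break
        k, core = k + 1, nxt
    if k == 0:
        return 0, 0.0
    return k, k * _density(core.number_of_nodes(), core.number_of_edges())


def vertex_weights(
    graph: nx.Graph, degree_cutoff: int = 2
) -> dict[str, VertexWeight]:
    """MCODE vertex weights over the whole graph.

    For each vertex of degree >= ``degree_cutoff``, the induced subgraph
    on the closed neighborhood (the vertex plus its neighbors) is cored;
    the weight is k_max times the density of that densest core.  Vertices
    below the cutoff weigh 0.
    """
    weights: dict[str, VertexWeight] = {}
    for v in graph.nodes:
        if graph.degree(v) < degree_cutoff:
            weights[v] = VertexWeight(v, 0, 0.0)
            continue
        closed = set(graph.neighbors(v)) | {v}
        k_max, w = _core_weight(graph.subgraph(closed))
        weights[v] = VertexWeight(v, k_max, w)
    return weights


def _make_cluster(graph: nx.Graph, members: Iterable[str], seed: str) -> Cluster:
    members = frozenset(members)
    sub = graph.subgraph(members)
    n, e = sub.number_of_nodes(), sub.number_of_edges()
    d = _density(n, e)
    return Cluster(members, seed, n, e, d, d * n)


def predict_complexes(
    graph: nx.Graph,
    weights: Mapping[str, VertexWeight],
    node_score_cutoff: float = 0.2,
    max_depth: int = 100,
) -> list[Cluster]:
    """Grow complexes from high-weight seeds (pre-post-processing).

    Seeds are visited in descending weight order (ties by node id); a
    breadth-first search from each seed absorbs unvisited neighbors whose
    weight is at least ``(1 - node_score_cutoff) * seed weight``.  Each
    vertex joins at most one complex, so complexes are pairwise disjoint.
    """
    if not 0 <= node_score_cutoff < 1:
        raise ValueError("node_score_cutoff must lie in [0, 1)")
    w = {v: weights[v].weight for v in graph.nodes}
    visited: set[str] = set()
    clusters: list[Cluster] = []
    for seed in sorted(graph.nodes, key=lambda v: (-w[v], str(v))):
        if seed in visited or w[seed] <= 0:
            continue
        threshold = (1.0 - node_score_cutoff) * w[seed]
        members = {seed}
        visited.add(seed)
        queue = deque([(seed, 0)])
        while queue:
            node, depth = queue.popleft()
            if depth >= max_depth:
                continue
            for u in graph.neighbors(node):
                if u in visited or w[u] < threshold:
                    continue
                visited.add(u)
                members.add(u)
                queue.append((u, depth + 1))
        clusters.append(_make_cluster(graph, members, seed))
    return clusters


def _fluff(
    graph: nx.Graph, members: set, fluff_threshold: float
) -> set:
    added = set()
    for v in members:
        for u in graph.neighbors(v):
            if u in members or u in added:
                continue
            closed = set(graph.neighbors(u)) | {u}
            sub = graph.subgraph(closed)
            if _density(sub.number_of_nodes(), sub.number_of_edges()) > fluff_threshold:
                added.add(u)
    return members | added


def postprocess(
    clusters: Sequence[Cluster],
    graph: nx.Graph,
    require_core: int = 2,
    haircut: bool = True,
    fluff: bool = False,
    fluff_threshold: float = 0.2,
) -> list[Cluster]:
    """Haircut / core filter / optional fluff.

    Each complex is replaced by the ``require_core``-core of its induced
    subgraph (iterated pendant removal); complexes without such a core are
    discarded.  With ``haircut=False`` the core is only required to
    exist, not substituted.  Fluff adds neighbors whose closed
    neighborhood density exceeds ``fluff_threshold`` and may make
    complexes overlap; it runs before the haircut, as in the original
    plug-in.
    """
    out: list[Cluster] = []
    for cl in clusters:
        members = set(cl.members)
        if fluff:
            members = _fluff(graph, members, fluff_threshold)
        core = k_core(graph.subgraph(members), require_core)
        if core.number_of_nodes() == 0:
            continue
        kept = set(core.nodes) if haircut else members
        out.append(_make_cluster(graph, kept, cl.seed))
    return out


def cluster_score(n: int, e: int) -> float:
    """Complex quality: density x size, ``n * 2e / (n(n-1))``."""
    if n < 2:
        raise ValueError(f"cluster score undefined for n={n} (< 2 nodes)")
    if not 0 <= e <= n * (n - 1) // 2:
        raise ValueError(f"edge count {e} impossible for {n} nodes")
    return n * _density(n, e)


def rank_clusters(clusters: Iterable[Cluster]) -> list[Cluster]:
    """Descending by score; ties by descending size, then seed id."""
    return sorted(clusters, key=lambda c: (-c.score, -c.n, str(c.seed)))


def run_mcode(
    graph: nx.Graph,
    node_score_cutoff: float = 0.2,
    core_k: int = 2,
    degree_cutoff: int = 2,
    haircut: bool = True,
    fluff: bool = False,
    max_depth: int = 100,
) -> list[Cluster]:
    """Full MCODE pass: weight, predict, post-process, rank."""
    weights = vertex_weights(graph, degree_cutoff)
    raw = predict_complexes(graph, weights, node_score_cutoff, max_depth)
    return rank_clusters(postprocess(raw, graph, core_k, haircut, fluff))


def clusters_table(clusters: Sequence[Cluster]) -> pd.DataFrame:
    """Ranked cluster table: rank, score (3 decimals), n, e, seed, members."""
    rows = [
        {
            "rank": i + 1,
            "score": round(c.score, 3),
            "nodes": c.n,
            "edges": c.e,
            "seed": c.seed,
            "members": ",".join(sorted(map(str, c.members))),
        }
        for i, c in enumerate(clusters)
    ]
    return pd.DataFrame(
        rows, columns=["rank", "score", "nodes", "edges", "seed", "members"]
    )


def write_clusters(clusters: Sequence[Cluster], path: str | Path) -> None:
    clusters_table(clusters).to_csv(path, sep="\t", index=False)
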