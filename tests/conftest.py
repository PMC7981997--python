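import itertools

import networkx as nx
import numpy as np
import pytest

from npharm import synthetic
from npharm.chem_filter import CompoundDescriptors


def make_descriptors(**overrides) -> CompoundDescriptors:
    """A compound sitting comfortably inside every rule box (all rules pass,
    bioavailability 0.55)."""
    base = dict(
        compound_id="c1",
        name="c1",
        mw=350.0,
        mlogp=2.0,
        wlogp=2.0,
        xlogp=2.0,
        hbd=2,
        hba=5,
        tpsa=60.0,
        rotatable_bonds=5,
        molar_refractivity=85.0,
        heavy_atoms=45,
        rings=4,
        carbons=20,
        heteroatoms=5,
        ionization_class="neutral",
    )
    base.update(overrides)
    return CompoundDescriptors(**base)


@pytest.fixture(scope="session")
def bundle():
    """One default synthetic input bundle, shared across the suite."""
    return synthetic.generate_all(seed=1)


# ---------------------------------------------------------------------------
# brute-force graph oracles, independent of the implementations they check


def oracle_shortest_distances(graph: nx.Graph) -> dict:
    """All-pairs shortest-path lengths by Floyd-Warshall over an adjacency
    matrix (no graph-library shortest-path code)."""
    nodes = sorted(graph.nodes)
    index = {v: i for i, v in enumerate(nodes)}
    n = len(nodes)
    dist = np.full((n, n), np.inf)
    np.fill_diagonal(dist, 0.0)
    for a, b in graph.edges:
        dist[index[a], index[b]] = dist[index[b], index[a]] = 1.0
    for k in range(n):
        dist = np.minimum(dist, dist[:, k, None] + dist[None, k, :])
    return {(a, b): dist[index[a], index[b]] for a in nodes for b in nodes}


def _all_simple_paths(adj: dict, s, t) -> list:
    """All simple s->t paths by explicit depth-first enumeration."""
    out, stack = [], [(s, [s])]
    while stack:
        v, path = stack.pop()
        if v == t:
            out.append(path)
            continue
        for u in adj[v]:
            if u not in path:
                stack.append((u, path + [u]))
    return out


def oracle_betweenness(graph: nx.Graph, normalized: bool = True) -> dict:
    """Betweenness by exhaustive enumeration of every shortest path."""
    nodes = sorted(graph.nodes)
    adj = {v: sorted(graph.neighbors(v)) for v in nodes}
    acc = {v: 0.0 for v in nodes}
    for s, t in itertools.combinations(nodes, 2):
        paths = _all_simple_paths(adj, s, t)
        if not paths:
            continue
        shortest = min(len(p) for p in paths)
        geodesics = [p for p in paths if len(p) == shortest]
        for v in nodes:
            if v in (s, t):
                continue
            through = sum(1 for p in geodesics if v in p)
            acc[v] += through / len(geodesics)
    if normalized:
        for comp in nx.connected_components(graph):
            n_c = len(comp)
            scale = (n_c - 1) * (n_c - 2) / 2
            for v in comp:
                acc[v] = acc[v] / scale if scale > 0 else 0.0
    return acc


def oracle_closeness(graph: nx.Graph) -> dict:
    """Within-component normalized closeness from Floyd-Warshall distances."""
    dist = oracle_shortest_distances(graph)
    out = {}
    for comp in nx.connected_components(graph):
        comp = sorted(comp)
        for v in comp:
            total = sum(dist[v, u] for u in comp if u != v)
            out[v] = (len(comp) - 1) / total if total > 0 else 0.0
    return out


def oracle_k_core_members(graph: nx.Graph, k: int) -> set:
    """The k-core as the union of every vertex subset whose induced subgraph
    has minimum degree >= k (exhaustive subset search)."""
    nodes = sorted(graph.nodes)
    best: set = set()
    for r in range(1, len(nodes) + 1):
        for subset in itertools.combinations(nodes, r):
            sub = graph.subgraph(subset)
            if all(d >= k for _, d in sub.degree()):
                best |= set(subset)
    return best


def connected_atlas_graphs(max_nodes: int = 7):
    """Every connected graph on 3..max_nodes vertices, from the graph atlas."""
    from networkx.generators.atlas import graph_atlas_g

    for g in graph_atlas_g():
        if 3 <= g.number_of_nodes() <= max_nodes and nx.is_connected(g):
            yield g
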