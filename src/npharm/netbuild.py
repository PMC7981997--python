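"""Typed network assembly, topological coefficients and hub selection.

Networks are undirected :class:`networkx.Graph` objects whose nodes carry
a ``kind`` attribute (compound | target | pathway | protein) and whose
edges may carry a ``confidence`` attribute in [0, 1].

Topological coefficients follow the conventions of the common network
analysis tools: degree is the incident-edge count; betweenness is the
Brandes pair-dependency accumulation normalized by (n-1)(n-2)/2 within
each connected component; closeness is the within-component normalized
form (n_c - 1) / sum of shortest-path distances.  The literal reciprocal
distance sum is available behind ``literal=True`` for closeness and
``normalized=False`` for betweenness; disconnected graphs are handled per
component and cross-component distances are never summed.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)

COMPOUND = "compound"
TARGET = "target"
PATHWAY = "pathway"
PROTEIN = "protein"


def build_bipartite(mapping: Mapping[str, set[str]]) -> nx.Graph:
    """Compound-target network from per-compound target sets.

    Every compound key becomes a node (compounds whose set is empty appear
    isolated, mirroring source tables that list a compound without any
    passing prediction); every distinct target becomes a node; one edge
    per (compound, target) pair.  Node count is therefore
    #compounds + #distinct targets.

    Raises
    ------
    ValueError
        If a compound id collides with a target symbol (the two node
        namespaces must be disjoint).
    """
    if not mapping:
        raise ValueError("empty compound->target mapping")
    targets: set[str] = set()
    for genes in mapping.values():
        targets |= genes
    collisions = sorted(set(mapping) & targets)
    if collisions:
        raise ValueError(
            f"compound ids collide with target symbols: {collisions}"
        )
    net = nx.Graph()
    net.add_nodes_from(((c, {"kind": COMPOUND}) for c in mapping))
    net.add_nodes_from(((t, {"kind": TARGET}) for t in sorted(targets)))
    for compound, genes in mapping.items():
        net.add_edges_from((compound, g) for g in genes)
    return net


def build_tripartite(
    mapping: Mapping[str, set[str]],
    pathway_members: Mapping[str, set[str]],
) -> nx.Graph:
    """Compound-target-pathway network.

    The target layer is the union of the compound target sets; pathway
    members outside that layer are dropped with a warning.  Pathways left
    without any member edge are omitted.
    """
    net = build_bipartite(mapping)
    for pathway, members in pathway_members.items():
        kept = {m for m in members if net.nodes.get(m, {}).get("kind") == TARGET}
        dropped = set(members) - kept
        if dropped:
            logger.warning(
                "pathway %r: %d member(s) absent from the target layer, "
                "edges dropped", pathway, len(dropped),
            )
        if kept:
            net.add_node(pathway, kind=PATHWAY)
            net.add_edges_from((pathway, m) for m in kept)
    return net


def class_counts(net: nx.Graph) -> dict[str, int]:
    counts: dict[str, int] = {}
    for _, kind in net.nodes(data="kind"):
        counts[kind] = counts.get(kind, 0) + 1
    return counts


def degree(net: nx.Graph) -> dict[str, int]:
    """Incident-edge count per node."""
    return {v: d for v, d in net.degree()}


def betweenness(net: nx.Graph, normalized: bool = True) -> dict[str, float]:
    """Shortest-path betweenness, computed per connected component.

    Normalization divides each node's accumulated pair dependency by
    (n_c - 1)(n_c - 2) / 2, the number of ordered-free pairs of other
    nodes in its component; components with fewer than 3 nodes score 0.
    """
    out: dict[str, float] = {}
    for comp in nx.connected_components(net):
        sub = net.subgraph(comp)
        if len(comp) < 3:
            out.update({v: 0.0 for v in comp})
            continue
        out.update(nx.betweenness_centrality(sub, normalized=normalized))
    return out


def closeness(net: nx.Graph, literal: bool = False) -> dict[str, float]:
    """Closeness centrality, computed within each connected component.

    Default: (n_c - 1) / sum of distances, in [0, 1].  With
    ``literal=True`` the raw reciprocal 1 / sum of distances is returned.
    Isolated nodes score 0.
    """
    out: dict[str, float] = {}
    for comp in nx.connected_components(net):
        sub = net.subgraph(comp)
        if len(comp) == 1:
            out[next(iter(comp))] = 0.0
            continue
        for v in comp:
            total = sum(nx.single_source_shortest_path_length(sub, v).values())
            out[v] = (1.0 if literal else len(comp) - 1) / total
    return out


def metrics_table(net: nx.Graph) -> pd.DataFrame:
    """Per-node table of id, kind, degree, betweenness and closeness."""
    deg = degree(net)
    btw = betweenness(net)
    clo = closeness(net)
    rows = [
        {
            "id": v,
            "kind": net.nodes[v].get("kind", ""),
            "degree": deg[v],
            "betweenness": btw[v],
            "closeness": clo[v],
        }
        for v in sorted(net.nodes)
    ]
    return pd.DataFrame(rows)


def mean_metrics(
    net: nx.Graph, subset: Iterable[str]
) -> tuple[float, float, float]:
    """Arithmetic means of (degree, betweenness, closeness) over a node subset."""
    subset = list(subset)
    if not subset:
        raise ValueError("empty node subset")
    missing = [v for v in subset if v not in net]
    if missing:
        raise ValueError(f"nodes absent from network: {missing}")
    deg, btw, clo = degree(net), betweenness(net), closeness(net)
    k = len(subset)
    return (
        sum(deg[v] for v in subset) / k,
        sum(btw[v] for v in subset) / k,
        sum(clo[v] for v in subset) / k,
    )


def filter_ppi(edges: pd.DataFrame, threshold: float = 0.7) -> nx.Graph:
    """High-confidence PPI network from a scored edge table.

    Keeps edges with confidence strictly greater than ``threshold``
    (duplicate pairs keep the highest score; self-loops are dropped);
    proteins without a surviving edge do not appear.
    """
    conf = pd.to_numeric(edges["confidence"], errors="coerce")
    if not conf.between(0.0, 1.0).all():
        raise ValueError("confidence scores must lie in [0, 1]")
    net = nx.Graph()
    kept = edges.loc[conf > threshold]
    for a, b, c in zip(kept["protein_a"], kept["protein_b"], kept["confidence"]):
        a, b = str(a), str(b)
        if a == b:
            continue
        prev = net.get_edge_data(a, b)
        if prev is None or prev["confidence"] < c:
            net.add_edge(a, b, confidence=float(c))
    nx.set_node_attributes(net, PROTEIN, "kind")
    return net


def top_k_by_degree(net: nx.Graph, k: int = 20) -> list[str]:
    """The ``min(k, n)`` highest-degree nodes.

    Ties are broken by descending betweenness, then lexicographic id.
    """
    deg = degree(net)
    btw = betweenness(net)
    ranked = sorted(net.nodes, key=lambda v: (-deg[v], -btw[v], v))
    return ranked[: min(k, len(ranked))]


def write_sif(net: nx.Graph, path: str | Path, relation: str = "pp") -> None:
    """Simple interaction format: node <TAB> relation <TAB> node."""
    with open(path, "w") as fh:
        for a, b in sorted(tuple(sorted(e)) for e in net.edges):
            fh.write(f"{a}\t{relation}\t{b}\n")
        for v in sorted(nx.isolates(net)):
            fh.write(f"{v}\n")


def write_graphml(net: nx.Graph, path: str | Path) -> None:
    nx.write_graphml(net, path)


def write_metrics(net: nx.Graph, path: str | Path) -> None:
    metrics_table(net).to_csv(path, sep="\t", index=False)
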