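"""Threshold graphs, connected components, naming, and MST reduction.

Vertices from all time points are pooled into one undirected graph; an
edge joins two sequences whose Levenshtein distance is at or below the
chosen threshold. Connected components are the putative clonal lineages.
Components are named by size (most vertices -> id 1); singleton components
carry no homology signal and are filtered out before lineage analysis.
Minimum spanning trees give a sparse, drawable skeleton of each component.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx
import pandas as pd

from .distance import NeighborPair
from .repertoire import RepertoireCollection


@dataclass
class Component:
    component_id: int
    vertex_ids: frozenset[int]
    edge_count: int

    @property
    def n_vertices(self) -> int:
        return len(self.vertex_ids)


def build_graph(
    collection: RepertoireCollection,
    pairs: Iterable[NeighborPair],
    t: int,
) -> nx.Graph:
    """Undirected graph on all pooled vertices with edges of LD <= t.

    ``pairs`` must have been enumerated at a threshold >= t; edges above t
    are dropped here, so one pair enumeration serves a whole sweep.
    """
    g = nx.Graph(threshold=t)
    g.add_nodes_from(v.vertex_id for v in collection.vertices)
    for a, b, ld in pairs:
        if ld <= t and a != b:
            g.add_edge(a, b, ld=ld)
    return g


def components(graph: nx.Graph) -> list[Component]:
    """Connected components with provisional ids (1.. by smallest member)."""
    comps = sorted(nx.connected_components(graph), key=min)
    return [
        Component(
            component_id=i + 1,
            vertex_ids=frozenset(nodes),
            edge_count=graph.subgraph(nodes).number_of_edges(),
        )
        for i, nodes in enumerate(comps)
    ]


def filter_singletons(comps: Sequence[Component]) -> tuple[list[Component], dict]:
    """Drop single-vertex components; return survivors and the census.

    The census satisfies ``total - singletons == retained`` by construction.
    """
    retained = [c for c in comps if c.n_vertices >= 2]
    census = {
        "total_components": len(comps),
        "singleton_components": len(comps) - len(retained),
        "retained_components": len(retained),
    }
    return retained, census


def name_components(
    comps: Sequence[Component], collection: RepertoireCollection
) -> list[Component]:
    """Assign ids 1.. by decreasing vertex count (pooled over time points).

    Ties break by larger total read count, then by the lexicographically
    smallest member sequence, so naming is fully deterministic.
    """
    by_id = {v.vertex_id: v for v in collection.vertices}

    def key(c: Component):
        total_reads = sum(by_id[i].total_count for i in c.vertex_ids)
        min_seq = min(by_id[i].sequence for i in c.vertex_ids)
        return (-c.n_vertices, -total_reads, min_seq)

    ordered = sorted(comps, key=key)
    return [
        Component(component_id=i + 1, vertex_ids=c.vertex_ids, edge_count=c.edge_count)
        for i, c in enumerate(ordered)
    ]


def mst(component: Component, pairs: Iterable[NeighborPair]) -> list[NeighborPair]:
    """Minimum spanning tree of one component by Kruskal's algorithm.

    Edges are considered in canonical (ld, a, b) order, which fixes the
    tree whenever weights tie. Raises ``ValueError`` if the supplied pairs
    do not connect the component (a contract violation upstream).
    """
    members = component.vertex_ids
    internal = sorted(
        p for p in pairs if p.vertex_id_a in members and p.vertex_id_b in members
    )
    internal.sort(key=lambda p: (p.ld, p.vertex_id_a, p.vertex_id_b))
    parent = {v: v for v in members}

    def find(v):
        while parent[v] != v:
            parent[v] = parent[parent[v]]
            v = parent[v]
        return v

    tree: list[NeighborPair] = []
    for p in internal:
        ra, rb = find(p.vertex_id_a), find(p.vertex_id_b)
        if ra != rb:
            parent[ra] = rb
            tree.append(p)
            if len(tree) == len(members) - 1:
                break
    if len(tree) != len(members) - 1:
        raise ValueError(
            f"component {component.component_id} is not connected by the "
            f"supplied pairs ({len(tree)} tree edges for {len(members)} vertices)"
        )
    return tree


# -- exports -----------------------------------------------------------


def membership_frame(comps: Sequence[Component]) -> pd.DataFrame:
    rows = [
        (vid, c.component_id)
        for c in comps
        for vid in sorted(c.vertex_ids)
    ]
    rows.sort()
    return pd.DataFrame(rows, columns=["vertex_id", "component_id"])


def write_graphml(graph: nx.Graph, path) -> None:
    nx.write_graphml(graph, path)


def write_membership_tsv(comps: Sequence[Component], path) -> None:
    membership_frame(comps).to_csv(path, sep="\t", index=False)
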