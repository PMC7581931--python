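"""Environment co-occurrence network from category sequence compositions.

Each environmental category is described by the composition of
representative 16S entries its reference sequences map to.  Categories
whose member sequences co-occur — i.e. map to overlapping sets of
representatives — get a small Bray-Curtis dissimilarity; drawing an
edge wherever the dissimilarity is strictly below a threshold (default
0.9) yields an undirected co-occurrence network over environments.

Centrality is quantified by pair counting: the betweenness of a node is
the number of connected node pairs with at least one shortest path
through it.  This differs from Freeman betweenness, which credits a
node fractionally by the share of shortest paths through it; the
fractional variant is available via ``fractional=True``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial import distance as ssd

from .reference_db import ReferenceDatabase
from .search import SearchParams, align_pair

logger = logging.getLogger(__name__)

__all__ = [
    "CategoryNetwork",
    "composition_matrix",
    "cluster_representatives",
    "bray_curtis",
    "dissimilarity_matrix",
    "build_network",
    "betweenness_pairs",
    "write_network",
]


@dataclass(frozen=True)
class CategoryNetwork:
    """A thresholded Bray-Curtis co-occurrence network over categories."""

    dissimilarity: pd.DataFrame
    graph: nx.Graph
    threshold: float
    betweenness: dict[str, float]

    @property
    def nodes(self) -> list[str]:
        return list(self.dissimilarity.index)

    @property
    def edges(self) -> list[tuple[str, str]]:
        return sorted(tuple(sorted(e)) for e in self.graph.edges)


def composition_matrix(
    db: ReferenceDatabase, mapping: Mapping[str, str]
) -> pd.DataFrame:
    """Count, per category, how many references map to each representative.

    ``mapping`` sends reference ids to representative entry ids;
    references absent from the mapping are dropped with a warning, and
    categories whose references are all unmapped are excluded.
    """
    unknown = [r for r in mapping if r not in db]
    if unknown:
        raise ValueError(f"mapping references unknown ids: {sorted(unknown)}")
    pairs = [
        (ref.category, mapping[ref.sequence_id])
        for ref in db
        if ref.sequence_id in mapping
    ]
    n_dropped = len(db) - len(pairs)
    if n_dropped:
        logger.warning("%d unmapped reference(s) dropped", n_dropped)
    if not pairs:
        raise ValueError("no mapped references")
    cats, reps = zip(*pairs)
    table = pd.crosstab(pd.Index(cats, name="category"),
                        pd.Index(reps, name="representative"))
    return table.loc[table.sum(axis=1) > 0]


def cluster_representatives(
    db: ReferenceDatabase,
    identity_threshold: float = 97.0,
    min_aligned_length: int = 150,
    params: SearchParams | None = None,
) -> dict[str, str]:
    """Greedy centroid clustering of reference sequences, in input order.

    A sequence joins the first existing centroid it aligns to at
    ``identity_threshold`` percent identity or better over at least
    ``min_aligned_length`` columns; otherwise it founds a new cluster.
    Deterministic for a fixed input order.  Returns reference id ->
    representative (centroid) id.
    """
    if len(db) == 0:
        raise ValueError("empty database")
    params = params or SearchParams()
    probe = SearchParams(
        min_aligned_length=max(min_aligned_length, params.kmer_size),
        min_percent_identity=identity_threshold,
        kmer_size=params.kmer_size,
        match=params.match,
        mismatch=params.mismatch,
        gap_open=params.gap_open,
        gap_extend=params.gap_extend,
        search_both_strands=params.search_both_strands,
    )
    centroids: list[tuple[str, str]] = []  # (id, sequence)
    mapping: dict[str, str] = {}
    for ref in db:
        assigned = None
        for cid, cseq in centroids:
            hit = align_pair(ref.sequence, cseq, probe)
            if hit is not None:
                assigned = cid
                break
        if assigned is None:
            centroids.append((ref.sequence_id, ref.sequence))
            assigned = ref.sequence_id
        mapping[ref.sequence_id] = assigned
    return mapping


def bray_curtis(u, v) -> float:
    """Bray-Curtis dissimilarity 1 - 2*sum(min(u, v)) / (sum(u) + sum(v))."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValueError("vectors must have the same length")
    if (u < 0).any() or (v < 0).any():
        raise ValueError("vectors must be non-negative")
    if u.sum() <= 0 or v.sum() <= 0:
        raise ValueError("zero-sum vector has no Bray-Curtis dissimilarity")
    return float(ssd.braycurtis(u, v))


def dissimilarity_matrix(composition: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Bray-Curtis dissimilarities between category compositions."""
    cats = list(composition.index)
    mat = np.zeros((len(cats), len(cats)))
    vectors = composition.to_numpy(dtype=float)
    for i in range(len(cats)):
        for j in range(i + 1, len(cats)):
            mat[i, j] = mat[j, i] = bray_curtis(vectors[i], vectors[j])
    return pd.DataFrame(mat, index=cats, columns=cats)


def betweenness_pairs(graph: nx.Graph, fractional: bool = False) -> dict:
    """Betweenness of every node, counted over connected node pairs.

    Pair-counting (default): node v scores 1 for each unordered pair
    {s, t} (s, t distinct from v and from each other, connected to each
    other) with at least one shortest s-t path passing through v.
    ``fractional=True`` switches to standard (unnormalized) Freeman
    betweenness, where v is credited the fraction of shortest s-t paths
    through it.
    """
    if fractional:
        return nx.betweenness_centrality(graph, normalized=False)
    dist = dict(nx.all_pairs_shortest_path_length(graph))
    nodes = list(graph.nodes)
    counts = {v: 0 for v in nodes}
    for i, s in enumerate(nodes):
        ds = dist[s]
        for t in nodes[i + 1:]:
            if t not in ds:
                continue  # disconnected pair
            d_st = ds[t]
            dt = dist[t]
            for v in nodes:
                if v == s or v == t:
                    continue
                if v in ds and v in dt and ds[v] + dt[v] == d_st:
                    counts[v] += 1
    return counts


def build_network(
    composition: pd.DataFrame,
    threshold: float = 0.9,
    fractional_betweenness: bool = False,
) -> CategoryNetwork:
    """Threshold Bray-Curtis dissimilarities into a co-occurrence network.

    An (undirected, unweighted) edge joins two categories iff their
    dissimilarity is strictly less than ``threshold``.
    """
    if len(composition.index) < 2:
        raise ValueError("need at least 2 categories to build a network")
    diss = dissimilarity_matrix(composition)
    graph = nx.Graph()
    graph.add_nodes_from(diss.index)
    cats = list(diss.index)
    for i, a in enumerate(cats):
        for b in cats[i + 1:]:
            d = diss.loc[a, b]
            if d < threshold:
                graph.add_edge(a, b, bray_curtis=float(d))
    betweenness = betweenness_pairs(graph, fractional=fractional_betweenness)
    return CategoryNetwork(
        dissimilarity=diss, graph=graph, threshold=threshold,
        betweenness=betweenness,
    )


def write_network(net: CategoryNetwork, edges_path, nodes_path) -> None:
    """Export a network as edge-list and node TSVs."""
    with open(edges_path, "w") as fh:
        fh.write("node_a\tnode_b\tbray_curtis\n")
        for a, b in net.edges:
            fh.write(f"{a}\t{b}\t{net.graph.edges[a, b]['bray_curtis']:.6f}\n")
    with open(nodes_path, "w") as fh:
        fh.write("node\tbetweenness\n")
        for node in net.nodes:
            fh.write(f"{node}\t{net.betweenness[node]}\n")
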