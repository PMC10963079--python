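"""Comparative topology statistics between a ssDDN and its ssDDN+.

Degree-rank changes, category-pair edge matrices, cross-category edge
fractions, connected-node counts, per-biomarker edge attribution, induced
subnetworks and the focal-trait adjacency report.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd

from .network import pair_key

#: Upper-triangle codes in :func:`adjacency_matrix_report`.
ADJ_NONE, ADJ_DIRECT, ADJ_FOCAL = 0, 1, 2


def competition_ranks(degrees: Mapping[str, int]) -> dict[str, int]:
    """Competition ("min") ranking: rank 1 = highest degree, ties share rank."""
    vals = np.array(list(degrees.values()))
    return {node: int(1 + (vals > deg).sum()) for node, deg in degrees.items()}


def degree_rank_change(ssddn: nx.Graph, ssddnplus: nx.Graph) -> pd.DataFrame:
    """Per-disease degrees and ranks in both networks.

    ``rank_change`` is positive when a disease moves up (towards rank 1) in
    the augmented network; ``newly_connected`` flags diseases isolated in the
    ssDDN that gained at least one edge in the ssDDN+.
    """
    if set(ssddn.nodes) != set(ssddnplus.nodes):
        raise ValueError("node sets differ between the two graphs")
    deg0 = dict(ssddn.degree())
    deg1 = dict(ssddnplus.degree())
    r0 = competition_ranks(deg0)
    r1 = competition_ranks(deg1)
    nodes = sorted(ssddn.nodes)
    return pd.DataFrame({
        "degree_ssddn": [deg0[n] for n in nodes],
        "degree_ssddnplus": [deg1[n] for n in nodes],
        "rank_ssddn": [r0[n] for n in nodes],
        "rank_ssddnplus": [r1[n] for n in nodes],
        "rank_change": [r0[n] - r1[n] for n in nodes],
        "newly_connected": [deg0[n] == 0 and deg1[n] > 0 for n in nodes],
    }, index=pd.Index(nodes, name="disease"))


EdgeSelector = Callable[[dict], bool]

_SELECTORS: dict[str, EdgeSelector] = {
    "all": lambda d: True,
    "direct": lambda d: d["is_direct"],
    "indirect": lambda d: bool(d["linking_traits"]),
    "direct_only": lambda d: d["edge_class"] == "direct",
    "indirect_only": lambda d: d["edge_class"] == "indirect",
    "both": lambda d: d["edge_class"] == "both",
}


def _selector(edge_class) -> EdgeSelector:
    if callable(edge_class):
        return edge_class
    try:
        return _SELECTORS[edge_class]
    except KeyError:
        raise ValueError(f"unknown edge selector {edge_class!r}; "
                         f"use one of {sorted(_SELECTORS)} or a callable") from None


def _node_categories(g: nx.Graph) -> dict[str, str]:
    cats = {}
    for n, data in g.nodes(data=True):
        cat = data.get("category")
        if cat is None or (isinstance(cat, float) and math.isnan(cat)):
            raise ValueError(f"node {n!r} has no category attribute")
        cats[n] = str(cat)
    return cats


@dataclass
class CategoryPairMatrix:
    """Edge counts between (and within) disease categories.

    ``normalized`` divides each count by the number of node pairs exposed:
    n_a * n_b off-diagonal and C(n_a, 2) on the diagonal, correcting for
    unequal category sizes.
    """

    categories: list[str]
    raw: pd.DataFrame
    normalized: pd.DataFrame
    node_counts: pd.Series

    def total_edges(self) -> int:
        """Sum of raw counts over unordered category pairs (diagonal once)."""
        mat = self.raw.to_numpy()
        return int(np.triu(mat).sum())


def category_pair_counts(g: nx.Graph, edge_class="all") -> CategoryPairMatrix:
    """Count selected edges by the unordered pair of endpoint categories."""
    select = _selector(edge_class)
    cats = _node_categories(g)
    categories = sorted(set(cats.values()))
    idx = pd.Index(categories, name="category")
    raw = pd.DataFrame(0, index=idx, columns=categories)
    for u, v, data in g.edges(data=True):
        if not select(data):
            continue
        a, b = cats[u], cats[v]
        raw.loc[a, b] += 1
        if a != b:
            raw.loc[b, a] += 1
    counts = pd.Series({c: sum(1 for n in cats if cats[n] == c) for c in categories},
                       name="n_nodes")
    denom = pd.DataFrame(np.outer(counts, counts), index=idx, columns=categories,
                         dtype=float)
    for c in categories:
        denom.loc[c, c] = counts[c] * (counts[c] - 1) / 2
    normalized = raw / denom.where(denom > 0)
    return CategoryPairMatrix(categories=categories, raw=raw,
                              normalized=normalized, node_counts=counts)


def cross_category_fraction(g: nx.Graph) -> float:
    """Fraction of edges whose endpoints lie in different categories.

    NaN when the graph has no edges (0/0 is undefined).
    """
    cats = _node_categories(g)
    n_edges = g.number_of_edges()
    if n_edges == 0:
        return float("nan")
    cross = sum(1 for u, v in g.edges() if cats[u] != cats[v])
    return cross / n_edges


def connected_node_count(g: nx.Graph) -> int:
    """Number of nodes with at least one incident edge."""
    return sum(1 for _, deg in g.degree() if deg > 0)


def biomarker_contribution(ssddn: nx.Graph, ssddnplus: nx.Graph,
                           traits: Iterable[str] | None = None) -> pd.DataFrame:
    """Per-trait attribution of indirect edges.

    ``new_edges`` counts indirect edges listing the trait that are absent from
    the direct edge set; ``redundant_edges`` counts those coinciding with a
    pre-existing direct edge.  Attribution is non-exclusive: an edge supported
    by several traits credits each of them, so per trait
    new + redundant equals its total edge memberships in E+.
    """
    direct_pairs = {pair_key(str(a), str(b)) for a, b in ssddn.edges()}
    rows: dict[str, dict[str, int]] = {
        t: {"new_edges": 0, "redundant_edges": 0} for t in (traits or [])
    }
    for a, b, data in ssddnplus.edges(data=True):
        lt = data.get("linking_traits", [])
        if not lt:
            continue
        bucket = "redundant_edges" if pair_key(str(a), str(b)) in direct_pairs else "new_edges"
        for t in lt:
            rows.setdefault(t, {"new_edges": 0, "redundant_edges": 0})[bucket] += 1
    df = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    df.index.name = "trait"
    if df.empty:
        df = pd.DataFrame(columns=["new_edges", "redundant_edges"],
                          index=pd.Index([], name="trait"), dtype=int)
    df["total_memberships"] = df["new_edges"] + df["redundant_edges"]
    return df


def extract_subnetwork(g: nx.Graph, node_subset: Iterable[str]) -> nx.Graph:
    """Induced subgraph on ``node_subset`` with edge provenance preserved."""
    subset = list(node_subset)
    unknown = [n for n in subset if n not in g]
    if unknown:
        raise ValueError(f"unknown node(s) in subset: {unknown[:5]}")
    return g.subgraph(subset).copy()


@dataclass
class AdjacencyReport:
    """Square matrix over a node subset summarizing one biomarker's role.

    Upper triangle: 0 = no edge, 1 = direct edge, 2 = indirect edge created by
    the focal trait (a direct edge also linked by the focal trait stays 1).
    Lower triangle: number of linking biomarkers per disease pair.
    """

    nodes: list[str]
    focal_trait: str
    matrix: pd.DataFrame


def adjacency_matrix_report(g: nx.Graph, node_subset: Iterable[str],
                            focal_trait: str) -> AdjacencyReport:
    sub = extract_subnetwork(g, node_subset)
    nodes = list(node_subset)
    n = len(nodes)
    mat = np.zeros((n, n), dtype=int)
    for i in range(n):
        for j in range(i + 1, n):
            if not sub.has_edge(nodes[i], nodes[j]):
                continue
            data = sub.edges[nodes[i], nodes[j]]
            lt = data.get("linking_traits", [])
            if data.get("is_direct"):
                mat[i, j] = ADJ_DIRECT
            elif focal_trait in lt:
                mat[i, j] = ADJ_FOCAL
            mat[j, i] = len(lt)
    frame = pd.DataFrame(mat, index=nodes, columns=nodes)
    return AdjacencyReport(nodes=nodes, focal_trait=focal_trait, matrix=frame)


def compare_networks(ssddn: nx.Graph, ssddnplus: nx.Graph,
                     traits: Iterable[str] | None = None) -> dict:
    """Headline comparison of a network pair, as a JSON-ready dict."""
    from .network import edge_class_counts

    classes = edge_class_counts(ssddnplus)
    n_direct = ssddn.number_of_edges()
    n_total = ssddnplus.number_of_edges()
    new_edges = classes["indirect"]
    contrib = biomarker_contribution(ssddn, ssddnplus, traits=traits)
    have_cats = all("category" in d for _, d in ssddn.nodes(data=True))
    return {
        "n_nodes": ssddn.number_of_nodes(),
        "n_edges_ssddn": n_direct,
        "n_edges_ssddnplus": n_total,
        "n_new_edges": new_edges,
        "n_redundant_indirect_edges": classes["both"],
        "edge_increase_pct": (100.0 * new_edges / n_direct) if n_direct else float("nan"),
        "connected_nodes_ssddn": connected_node_count(ssddn),
        "connected_nodes_ssddnplus": connected_node_count(ssddnplus),
        "cross_category_fraction_ssddn":
            cross_category_fraction(ssddn) if have_cats else None,
        "cross_category_fraction_ssddnplus":
            cross_category_fraction(ssddnplus) if have_cats else None,
        "edge_classes_ssddnplus": classes,
        "biomarker_contribution": {
            t: {"new_edges": int(r["new_edges"]),
                "redundant_edges": int(r["redundant_edges"])}
            for t, r in contrib.iterrows()
        },
    }
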