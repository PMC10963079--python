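"""Construction of the shared-SNP disease network and its augmentation.

The baseline network (ssDDN) connects two diseases whenever they share at
least one genome-wide-significant, MAF-passing SNP (a *direct* edge).  The
augmented network (ssDDN+) adds an *indirect* edge between every pair of
diseases that are each significantly genetically correlated with the same
quantitative endophenotype — for each trait, a clique on its associated
diseases.  Both graphs are undirected and unweighted, but every edge carries
full provenance: the shared SNP list and/or the list of linking biomarkers.

Graphs are plain :class:`networkx.Graph` objects with the conventions:

* graph attribute ``kind`` in {"ssDDN", "ssDDN+"};
* node attributes ``category``, ``case_count``, ``description`` (optional);
* edge attributes ``is_direct`` (bool), ``shared_snps`` (list, non-empty iff
  direct), ``linking_traits`` (list), ``edge_class`` in
  {"direct", "indirect", "both"}.
"""

from __future__ import annotations

import csv
import hashlib
import json
import logging
from itertools import combinations
from pathlib import Path
from typing import Mapping

import networkx as nx
import numpy as np

from .ldsc import AssociationMatrix
from .sumstats import SumStatTable

log = logging.getLogger(__name__)

#: Genome-wide significance threshold on the association p-value (strict <).
GENOME_WIDE_P = 5e-8
#: Minor-allele-frequency threshold (strict >), applied per disease table.
DEFAULT_MAF = 0.05

Edge = tuple[str, str]


def pair_key(a: str, b: str) -> Edge:
    """Canonical unordered pair key."""
    if a == b:
        raise ValueError(f"self-pair {a!r} is not a valid edge")
    return (a, b) if a < b else (b, a)


def significant_snps(table: SumStatTable,
                     p_threshold: float = GENOME_WIDE_P,
                     maf_threshold: float = DEFAULT_MAF) -> set[str]:
    """Variants with p < p_threshold and minor allele frequency > maf_threshold."""
    for name, t in (("p_threshold", p_threshold), ("maf_threshold", maf_threshold)):
        if not (0 < t < 1):
            raise ValueError(f"{name} must lie in (0, 1), got {t}")
    pval = table.df["pval"].to_numpy(float)
    mask = (pval < p_threshold) & (table.maf > maf_threshold)
    return set(table.variant_ids[mask])


def build_direct_edges(sig_sets: Mapping[str, set[str]]) -> dict[Edge, list[str]]:
    """Direct edge set E: pairs of diseases with non-empty SNP intersection.

    Returns a mapping from the canonical disease pair to the sorted list of
    shared significant SNPs.
    """
    ids = sorted(sig_sets)
    if len(ids) < 2:
        raise ValueError("need at least two diseases to build edges")
    edges: dict[Edge, list[str]] = {}
    for a, b in combinations(ids, 2):
        shared = sig_sets[a] & sig_sets[b]
        if shared:
            edges[pair_key(a, b)] = sorted(shared)
    return edges


def build_indirect_edges(assoc: AssociationMatrix) -> dict[Edge, list[str]]:
    """Indirect edge set E+: per-trait cliques on associated diseases.

    For every trait, all unordered pairs of diseases associated with it gain
    an edge; an edge accumulates every trait that links it.  The association
    matrix is binary, so rg signs cannot (and do not) enter the rule.
    """
    edges: dict[Edge, list[str]] = {}
    for trait, diseases in assoc.trait_disease_sets().items():
        for a, b in combinations(sorted(diseases), 2):
            edges.setdefault(pair_key(a, b), []).append(trait)
    for key in edges:
        edges[key] = sorted(edges[key])
    return edges


def merge(direct: Mapping[Edge, list[str]],
          indirect: Mapping[Edge, list[str]],
          nodes: list[str] | None = None,
          node_attrs: Mapping[str, Mapping] | None = None) -> nx.Graph:
    """Union the direct and indirect edge sets into the augmented graph.

    An edge present in both sets keeps its shared SNPs *and* its linking
    traits and is classified ``"both"``.  Isolated nodes are retained (they
    matter for connected-node statistics).  The union accounting invariants
    are asserted on every call.
    """
    g = nx.Graph(kind="ssDDN+")
    universe = set(nodes or [])
    for a, b in list(direct) + list(indirect):
        universe.update((a, b))
    for node in sorted(universe):
        g.add_node(node, **dict((node_attrs or {}).get(node, {})))

    for (a, b), snps in direct.items():
        if not snps:
            raise ValueError(f"direct edge {a}-{b} carries no shared SNPs")
        g.add_edge(a, b, is_direct=True, shared_snps=list(snps),
                   linking_traits=[], edge_class="direct")
    for (a, b), traits in indirect.items():
        if not traits:
            raise ValueError(f"indirect edge {a}-{b} carries no linking traits")
        if g.has_edge(a, b):
            g.edges[a, b]["linking_traits"] = list(traits)
            g.edges[a, b]["edge_class"] = "both"
        else:
            g.add_edge(a, b, is_direct=False, shared_snps=[],
                       linking_traits=list(traits), edge_class="indirect")

    _check_union_accounting(g, direct, indirect)
    return g


def direct_graph(direct: Mapping[Edge, list[str]],
                 nodes: list[str] | None = None,
                 node_attrs: Mapping[str, Mapping] | None = None) -> nx.Graph:
    """The baseline ssDDN: direct edges only."""
    g = merge(direct, {}, nodes=nodes, node_attrs=node_attrs)
    g.graph["kind"] = "ssDDN"
    return g


def _check_union_accounting(g: nx.Graph,
                            direct: Mapping[Edge, list[str]],
                            indirect: Mapping[Edge, list[str]]) -> None:
    d_keys = {pair_key(a, b) for a, b in direct}
    i_keys = {pair_key(a, b) for a, b in indirect}
    n_expected = len(d_keys) + len(i_keys - d_keys)
    if g.number_of_edges() != n_expected:
        raise AssertionError(
            f"union accounting violated: |E~|={g.number_of_edges()} but "
            f"|E| + |E+ \\ E| = {n_expected}")
    classes = {"direct": 0, "indirect": 0, "both": 0}
    for _, _, data in g.edges(data=True):
        classes[data["edge_class"]] += 1
    if (classes["direct"] + classes["both"] != len(d_keys)
            or classes["indirect"] + classes["both"] != len(i_keys)
            or sum(classes.values()) != g.number_of_edges()):
        raise AssertionError(f"edge classes do not partition the edge set: {classes}")
    if any(a == b for a, b in g.edges()):
        raise AssertionError("self-loop found in merged graph")


def edge_class_counts(g: nx.Graph) -> dict[str, int]:
    counts = {"direct": 0, "indirect": 0, "both": 0}
    for _, _, data in g.edges(data=True):
        counts[data["edge_class"]] += 1
    return counts


def graph_signature(g: nx.Graph) -> str:
    """Deterministic content hash of nodes, edges and their attributes."""
    payload = {
        "kind": g.graph.get("kind"),
        "nodes": sorted((str(n), {k: v for k, v in sorted(attrs.items())})
                        for n, attrs in g.nodes(data=True)),
        "edges": sorted((*pair_key(str(a), str(b)),
                         {k: v for k, v in sorted(attrs.items())})
                        for a, b, attrs in g.edges(data=True)),
    }
    blob = json.dumps(payload, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()


_LIST_ATTRS = ("shared_snps", "linking_traits")


def write_graphml(g: nx.Graph, path) -> None:
    """GraphML export; list-valued edge attributes are ';'-joined strings."""
    h = g.copy()
    for _, _, data in h.edges(data=True):
        for key in _LIST_ATTRS:
            data[key] = ";".join(data.get(key, []))
    nx.write_graphml(h, path)


def read_graphml(path) -> nx.Graph:
    """Inverse of :func:`write_graphml` (';'-joined lists are split back)."""
    h = nx.read_graphml(path)
    g = nx.Graph(**h.graph)
    for n, attrs in h.nodes(data=True):
        g.add_node(n, **attrs)
    for a, b, data in h.edges(data=True):
        data = dict(data)
        for key in _LIST_ATTRS:
            raw = data.get(key, "")
            data[key] = raw.split(";") if raw else []
        data["is_direct"] = data.get("is_direct") in (True, "true", "True", 1, "1")
        g.add_edge(a, b, **data)
    return g


def write_edgelist_csv(g: nx.Graph, path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["disease_a", "disease_b", "edge_class",
                         "n_shared_snps", "shared_snps", "linking_traits"])
        for a, b in sorted(pair_key(str(u), str(v)) for u, v in g.edges()):
            data = g.edges[a, b]
            writer.writerow([a, b, data["edge_class"], len(data["shared_snps"]),
                             ";".join(data["shared_snps"]),
                             ";".join(data["linking_traits"])])


def write_netmage_csv(g: nx.Graph, path) -> None:
    """Flat edge map in the column layout NETMAGE-style viewers consume."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["node1", "node2", "snps"])
        for a, b in sorted(pair_key(str(u), str(v)) for u, v in g.edges()):
            writer.writerow([a, b, ";".join(g.edges[a, b]["shared_snps"])])
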