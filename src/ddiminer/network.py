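"""Term-article network construction and bipartite projection.

Significant substance terms and the articles of Group A form a two-mode
(bipartite) network: terms are actors, articles the groups they belong to,
and the term-article incidence matrix the membership matrix.  Projecting
onto the term mode yields a term-term graph in which two substances are
linked with weight equal to the number of Group-A articles whose substances
field contains both — the social-network view of which compounds and
proteins travel together through the DDI literature.  The queried drug is
always a node (its row is 1 for every article, by the corpus-membership
co-occurrence convention), so drug-protein-drug paths appear when networks
from two drug runs are merged on shared protein nodes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import IO, Mapping

import networkx as nx
import numpy as np

from .classify import classify_terms
from .records import MedlineRecord, match_key
from .sampling import CandidateResult

__all__ = [
    "TermArticleMatrix",
    "SubstanceNetwork",
    "select_network_terms",
    "build_incidence",
    "project",
    "export_graph",
    "merge_networks",
]


@dataclass
class TermArticleMatrix:
    """Binary incidence of terms (rows) over Group-A articles (columns)."""

    terms: list[str]
    pmids: list[str]
    incidence: np.ndarray  # bool, shape (len(terms), len(pmids))

    def row_sums(self) -> dict[str, int]:
        sums = self.incidence.sum(axis=1)
        return {t: int(s) for t, s in zip(self.terms, sums)}


@dataclass
class SubstanceNetwork:
    """Term-term projection: nodes carry a class, edges a shared-article weight."""

    nodes: list[tuple[str, str]]  # (term, klass)
    edges: list[tuple[str, str, int]]  # (term_i, term_j, weight), i < j in node order
    metadata: dict = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)


def select_network_terms(
    results: list[CandidateResult],
    alpha: float = 0.1,
    min_count: int = 3,
) -> list[str]:
    """Terms eligible for the network: p < alpha and x0 >= min_count."""
    return [r.term for r in results if r.p_value < alpha and r.x0 >= min_count]


def build_incidence(
    group_a: list[MedlineRecord],
    terms: list[str],
    queried_drug: str,
) -> TermArticleMatrix:
    """Binary term-article incidence over Group A.

    The queried drug is prepended as the first row and set to 1 everywhere:
    every article in the corpus co-occurs with it by membership.  Row order
    is drug-then-terms-as-given; column order follows the corpus.
    """
    if not terms:
        raise ValueError("terms must be non-empty")
    all_terms = [queried_drug, *terms]
    pmids = [rec.pmid for rec in group_a]
    incidence = np.zeros((len(all_terms), len(pmids)), dtype=bool)
    incidence[0, :] = True
    rec_keys = [rec.substance_keys() for rec in group_a]
    for i, term in enumerate(terms, start=1):
        key = match_key(term)
        for j, ks in enumerate(rec_keys):
            if key in ks:
                incidence[i, j] = True
    return TermArticleMatrix(all_terms, pmids, incidence)


def project(
    matrix: TermArticleMatrix,
    min_edge_weight: int = 1,
    classes: Mapping[str, str] | None = None,
) -> SubstanceNetwork:
    """One-mode projection: edge weight = number of shared articles.

    Weights are the off-diagonal entries of M @ M.T.  Edges below
    ``min_edge_weight`` are dropped (default 1: keep every co-membership).
    Node classes come from ``classes`` or the rule-based classifier.
    """
    if min_edge_weight < 1:
        raise ValueError("min_edge_weight must be >= 1")
    if classes is None:
        classes = {
            t: sc.klass for t, sc in classify_terms(matrix.terms).items()
        }
    co = matrix.incidence.astype(np.int64) @ matrix.incidence.astype(np.int64).T
    nodes = [(t, classes.get(t, "unknown")) for t in matrix.terms]
    edges = []
    n = len(matrix.terms)
    for i in range(n):
        for j in range(i + 1, n):
            w = int(co[i, j])
            if w >= min_edge_weight:
                edges.append((matrix.terms[i], matrix.terms[j], w))
    return SubstanceNetwork(
        nodes=nodes,
        edges=edges,
        metadata={"min_edge_weight": min_edge_weight, "n_articles": len(matrix.pmids)},
    )


def to_networkx(network: SubstanceNetwork) -> nx.Graph:
    """Undirected simple graph with node attribute ``klass`` and edge ``weight``."""
    g = nx.Graph()
    for term, klass in sorted(network.nodes):
        g.add_node(term, klass=klass)
    for u, v, w in sorted(network.edges):
        g.add_edge(u, v, weight=w)
    return g


def export_graph(network: SubstanceNetwork, format: str = "graphml") -> bytes:
    """Serialize the network as GraphML or a 3-column tab-separated edge list.

    Nodes and edges are emitted in sorted order so output is byte-stable.
    """
    if format == "graphml":
        g = to_networkx(network)
        return ("\n".join(nx.generate_graphml(g)) + "\n").encode("utf-8")
    if format == "edge_list":
        lines = ["source\ttarget\tweight"]
        for u, v, w in sorted(network.edges):
            lines.append(f"{u}\t{v}\t{w}")
        return ("\n".join(lines) + "\n").encode("utf-8")
    raise ValueError(f"unknown export format: {format!r}")


def merge_networks(
    a: SubstanceNetwork, b: SubstanceNetwork
) -> SubstanceNetwork:
    """Union of two drug networks, joining on shared nodes.

    Useful for drug-protein-drug motifs: run the pipeline for two drugs and
    merge; a protein significant for both links the two drug nodes.  Edge
    weights present in both inputs are summed (they count articles of
    different corpora).
    """
    nodes: dict[str, str] = {}
    for term, klass in [*a.nodes, *b.nodes]:
        nodes.setdefault(term, klass)
    weights: dict[tuple[str, str], int] = {}
    for u, v, w in [*a.edges, *b.edges]:
        key = (min(u, v), max(u, v))
        weights[key] = weights.get(key, 0) + w
    return SubstanceNetwork(
        nodes=sorted(nodes.items()),
        edges=[(u, v, w) for (u, v), w in sorted(weights.items())],
        metadata={"merged": True},
    )
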