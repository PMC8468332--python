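"""GO enrichment of lncRNA-neighboring genes.

Direct gene-to-term annotations are propagated up the is_a DAG (true-
path rule), each term present in the study set is tested for over-
representation with the one-sided Fisher exact test, and the
significant list is reduced to its most specific terms (those with no
significant descendant). KEGG-style pathway tallies reuse the same
counting without a DAG.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import networkx as nx
import obonet
from scipy.stats import fisher_exact


class GoDag:
    """A GO is_a DAG restricted to id, name and namespace.

    Wraps a networkx DiGraph with edges child -> parent.
    """

    def __init__(self, graph: nx.DiGraph):
        if not nx.is_directed_acyclic_graph(graph):
            raise ValueError("GO graph must be acyclic")
        for node in graph.nodes:
            if graph.out_degree(node) == 0 and graph.nodes[node].get("namespace") is None:
                raise ValueError(f"root {node} missing namespace")
        self.graph = graph

    @classmethod
    def from_obo(cls, path) -> "GoDag":
        multi = obonet.read_obo(path)
        g = nx.DiGraph()
        for node, data in multi.nodes(data=True):
            g.add_node(node, name=data.get("name"), namespace=data.get("namespace"))
        for child, parent, key in multi.edges(keys=True):
            if key == "is_a":
                g.add_edge(child, parent)
        return cls(g)

    def __contains__(self, term: str) -> bool:
        return term in self.graph

    def namespace(self, term: str) -> str | None:
        return self.graph.nodes[term].get("namespace")

    def ancestors(self, term: str) -> set[str]:
        """Terms reachable from ``term`` via is_a (the GO ancestors)."""
        return nx.descendants(self.graph, term)

    def descendants(self, term: str) -> set[str]:
        """Terms from which ``term`` is reachable (the GO descendants)."""
        return nx.ancestors(self.graph, term)


@dataclass
class EnrichmentResult:
    term: str
    k: int  # study genes carrying the term
    n: int  # study size
    K: int  # background genes carrying the term
    N: int  # background size
    p: float
    namespace: str | None = None
    most_specific: bool | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.k <= min(self.n, self.K)):
            raise ValueError("inconsistent contingency counts")
        if not (0 < self.p <= 1):
            raise ValueError("p must lie in (0, 1]")


def propagate_annotations(
    direct_map: dict[str, set[str]], dag: GoDag
) -> dict[str, set[str]]:
    """Annotate every gene to all is_a ancestors of its direct terms."""
    unknown = sorted(
        {t for terms in direct_map.values() for t in terms if t not in dag}
    )
    if unknown:
        raise ValueError(f"unknown GO terms: {unknown}")
    full: dict[str, set[str]] = {}
    cache: dict[str, set[str]] = {}
    for gene, terms in direct_map.items():
        out = set(terms)
        for t in terms:
            if t not in cache:
                cache[t] = dag.ancestors(t)
            out |= cache[t]
        full[gene] = out
    return full


def fisher_enrichment(
    study_genes: set[str],
    background_genes: set[str],
    full_map: dict[str, set[str]],
    dag: GoDag | None = None,
) -> list[EnrichmentResult]:
    """One-sided over-representation test per term present in the study.

    p = P(X >= k) for hypergeometric X with the study/background
    contingency. Results are sorted by ascending p, then term id.
    """
    if not study_genes or not background_genes:
        raise ValueError("study and background must be non-empty")
    if not study_genes <= background_genes:
        raise ValueError("study set must be a subset of the background")
    n = len(study_genes)
    N = len(background_genes)
    term_study: Counter = Counter()
    term_bg: Counter = Counter()
    for g in background_genes:
        for t in full_map.get(g, ()):
            term_bg[t] += 1
            if g in study_genes:
                term_study[t] += 1
    results = []
    for term, k in term_study.items():
        K = term_bg[term]
        _, p = fisher_exact(
            [[k, n - k], [K - k, (N - n) - (K - k)]], alternative="greater"
        )
        results.append(
            EnrichmentResult(
                term, k, n, K, N, float(p),
                namespace=dag.namespace(term) if dag and term in dag else None,
            )
        )
    results.sort(key=lambda r: (r.p, r.term))
    return results


def reduce_most_specific(
    results: list[EnrichmentResult],
    dag: GoDag,
    alpha: float = 0.05,
    top_n: int = 20,
) -> list[EnrichmentResult]:
    """Flag most-specific significant terms; return the top BP selection.

    A significant term is most specific iff none of its descendants is
    also significant. The returned list is the biological_process
    most-specific terms sorted by p, truncated to ``top_n``.
    """
    significant = {r.term for r in results if r.p < alpha}
    for r in results:
        if r.term not in significant:
            r.most_specific = False
        else:
            r.most_specific = not (dag.descendants(r.term) & significant)
    bp = [
        r
        for r in results
        if r.most_specific and r.namespace == "biological_process"
    ]
    bp.sort(key=lambda r: (r.p, r.term))
    return bp[:top_n]


def category_counts(
    genes: set[str], gene_to_category: dict[str, set[str]]
) -> Counter:
    """Flat category (e.g. pathway) membership tally over a gene set."""
    out: Counter = Counter()
    for g in genes:
        for c in gene_to_category.get(g, ()):
            out[c] += 1
    return out
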