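"""Functional-category enrichment among the most polymorphic genes.

Genes are split into the top decile by depth-corrected SNP abundance and the
remainder, and three families of Fisher's exact tests ask whether functional
categories are over-represented in the top set:

* **GO terms** — direct annotations are first propagated up the ontology
  (the true-path rule: a gene annotated to a term is annotated to all its
  ancestors); terms annotating fewer than ``nodesize`` genes (default 5) are
  skipped; the test is one-sided (over-representation) and raw p-values are
  reported.  Two hierarchy treatments are offered: ``classic`` (each term
  tested independently) and ``elim`` (terms processed leaves-upward; the
  genes of a term significant at ``alpha_elim`` are removed from its
  ancestors before those are tested, which decorrelates nested terms).
* **Gene families** — only families with at least two members in the top set
  are tested, two-sided, with optional Benjamini-Hochberg adjustment.
* **Binary flags** (orphan genes, conifer-specific genes) — a single
  two-sided test per flag, reported with the flag's proportion in each group.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Hashable, Iterable, Literal, Mapping, Sequence

import networkx as nx
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import DomainError, InputValidationError

__all__ = [
    "AnnotationTable",
    "EnrichmentResult",
    "propagate_go",
    "fisher_term_tests",
    "family_tests",
    "flag_tests",
]

Method = Literal["classic", "elim"]


@dataclass
class AnnotationTable:
    """Gene-level functional annotations.

    ``go`` maps gene id -> set of directly annotated GO term ids; ``family``
    maps gene id -> family id (genes absent from it are orphans when flagged
    so); ``orphan`` and ``conifer_specific`` are flag sets of gene ids.
    Orphan status and family membership are mutually exclusive.
    """

    go: dict[str, set[str]]
    family: dict[str, str]
    orphan: set[str]
    conifer_specific: set[str]

    def __post_init__(self) -> None:
        overlap = self.orphan & set(self.family)
        if overlap:
            raise InputValidationError(
                f"genes both orphan and in a family: {sorted(overlap)[:5]}"
            )


@dataclass
class EnrichmentResult:
    category: str
    a: int  # in top set and in category
    b: int  # in top set, not in category
    c: int  # not in top set, in category
    d: int  # neither
    odds_ratio: float
    p_value: float
    p_adjusted: float | None = None
    method: str = "classic"
    extra: dict | None = None

    @property
    def table(self) -> tuple[tuple[int, int], tuple[int, int]]:
        return ((self.a, self.b), (self.c, self.d))


def _dag_from_edges(edges: Iterable[tuple[str, str]]) -> nx.DiGraph:
    """Build the child -> parent ontology graph and reject cycles."""
    dag = nx.DiGraph()
    dag.add_edges_from(edges)
    if not nx.is_directed_acyclic_graph(dag):
        cycle = nx.find_cycle(dag)
        raise InputValidationError(f"GO edge list contains a cycle: {cycle[0]}")
    return dag


def propagate_go(
    direct: Mapping[str, set[str]], edges: Iterable[tuple[str, str]]
) -> dict[str, set[str]]:
    """Close annotations under the true-path rule.

    ``edges`` are (child, parent) pairs.  Each gene's annotation set is
    extended with every ancestor of each direct term; terms absent from the
    edge list are kept as-is.  The operation is idempotent.
    """
    dag = _dag_from_edges(edges)
    ancestors: dict[str, set[str]] = {}
    for term in dag.nodes:
        # parents lie downstream of child->parent edges
        ancestors[term] = nx.descendants(dag, term)
    full: dict[str, set[str]] = {}
    for gene, terms in direct.items():
        closed = set(terms)
        for term in terms:
            closed |= ancestors.get(term, set())
        full[gene] = closed
    return full


def _fisher(a: int, b: int, c: int, d: int, alternative: str) -> tuple[float, float]:
    res = stats.fisher_exact([[a, b], [c, d]], alternative=alternative)
    return float(res.statistic), float(res.pvalue)


def _contingency(
    members: set[str], top_set: set[str], universe: set[str]
) -> tuple[int, int, int, int]:
    a = len(members & top_set)
    b = len(top_set - members)
    c = len(members - top_set)
    d = len(universe) - a - b - c
    return a, b, c, d


def fisher_term_tests(
    annotations: Mapping[str, set[str]],
    top_set: set[str],
    universe: set[str],
    edges: Iterable[tuple[str, str]] | None = None,
    *,
    nodesize: int = 5,
    method: Method = "classic",
    alpha_elim: float = 0.01,
) -> list[EnrichmentResult]:
    """One-sided Fisher's exact test of every sufficiently large GO term.

    ``annotations`` must already be propagated (or pass ``edges`` to use the
    hierarchy; ``elim`` requires it).  The universe is the set of genes with
    at least one annotation in the tested namespace; only genes in it count.
    Raw p-values are reported, unadjusted, sorted ascending.
    """
    if not universe:
        raise DomainError("term tests require a non-empty universe")
    if not top_set <= universe:
        raise DomainError("top_set must be a subset of the universe")
    genes_by_term: dict[str, set[str]] = {}
    for gene, terms in annotations.items():
        if gene not in universe:
            continue
        for t in terms:
            genes_by_term.setdefault(t, set()).add(gene)
    testable = {t: g for t, g in genes_by_term.items() if len(g) >= nodesize}

    if method == "classic":
        ordered = sorted(testable)
        removed: dict[str, set[str]] = {t: set() for t in ordered}
    elif method == "elim":
        if edges is None:
            raise DomainError("elim requires the GO edge list")
        dag = _dag_from_edges(edges)
        for t in testable:
            if t not in dag:
                dag.add_node(t)
        # leaves first: topological order of the child->parent graph
        ordered = [t for t in nx.topological_sort(dag) if t in testable]
        removed = {t: set() for t in testable}
    else:
        raise DomainError(f"unknown method {method!r}")

    results: list[EnrichmentResult] = []
    for term in ordered:
        members = testable[term] - removed[term]
        a, b, c, d = _contingency(members, top_set, universe)
        odds, p = _fisher(a, b, c, d, "greater")
        results.append(
            EnrichmentResult(term, a, b, c, d, odds, p, method=method)
        )
        if method == "elim" and p < alpha_elim:
            for anc in nx.descendants(dag, term):
                if anc in removed:
                    removed[anc] |= testable[term]
    results.sort(key=lambda r: (r.p_value, r.category))
    return results


def family_tests(
    annotations: AnnotationTable,
    top_set: set[str],
    universe: set[str],
    *,
    min_in_top: int = 2,
    adjust: Literal["BH", "none"] = "BH",
) -> list[EnrichmentResult]:
    """Two-sided Fisher's exact tests of gene families.

    Only families with at least ``min_in_top`` members inside the top set are
    tested; with ``adjust="BH"`` Benjamini-Hochberg adjusted p-values are
    attached across the tested families.
    """
    members_by_family: dict[str, set[str]] = {}
    for gene, fam in annotations.family.items():
        if gene in universe:
            members_by_family.setdefault(fam, set()).add(gene)
    results: list[EnrichmentResult] = []
    for fam in sorted(members_by_family):
        members = members_by_family[fam]
        if len(members & top_set) < min_in_top:
            continue
        a, b, c, d = _contingency(members, top_set, universe)
        odds, p = _fisher(a, b, c, d, "two-sided")
        results.append(EnrichmentResult(fam, a, b, c, d, odds, p, method="classic"))
    if adjust == "BH" and results:
        adjusted = multipletests([r.p_value for r in results], method="fdr_bh")[1]
        for r, q in zip(results, adjusted):
            r.p_adjusted = float(q)
    results.sort(key=lambda r: (r.p_value, r.category))
    return results


def flag_tests(
    annotations: AnnotationTable,
    top_set: set[str],
    universe: set[str],
    flag: Literal["orphan", "conifer_specific"],
) -> EnrichmentResult:
    """Single two-sided Fisher's exact test of a binary gene flag.

    The result's ``extra`` dict reports the flag's proportion among top-set
    genes and among the remaining genes.
    """
    flagged = (
        annotations.orphan if flag == "orphan" else annotations.conifer_specific
    ) & universe
    a, b, c, d = _contingency(flagged, top_set, universe)
    if flagged:
        odds, p = _fisher(a, b, c, d, "two-sided")
    else:
        odds, p = float("nan"), 1.0
    n_top, n_rest = a + b, c + d
    extra = {
        "prop_top": a / n_top if n_top else float("nan"),
        "prop_rest": c / n_rest if n_rest else float("nan"),
        "defined": bool(flagged),
    }
    return EnrichmentResult(flag, a, b, c, d, odds, p, method="classic", extra=extra)
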