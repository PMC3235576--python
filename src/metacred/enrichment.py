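"""GO term over-representation, slim remapping and report collapsing.

A test gene set is compared against a background universe term by term
with the upper-tail hypergeometric test under the true-path rule (every
gene inherits its terms' is_a ancestors).  Raw P-values are Bonferroni
adjusted over the terms actually tested.  Significant terms are remapped
to their most-specific ancestors in a user-supplied slim, nonspecific
terms are blacklisted, groups shared by too few genes are dropped, and
synonymous terms (one term's gene set nested in another's within a slim
group) are collapsed into the superset term.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy.stats import hypergeom

from .io import AnnotationSet, OntologyDAG

__all__ = [
    "EnrichmentResult",
    "propagate_annotations",
    "term_enrichment",
    "select_significant",
    "slim_remap",
    "collapse_and_report",
]


@dataclass
class EnrichmentResult:
    """Per-term over-representation outcome (counts are post-propagation)."""

    term_id: str
    term_name: str
    k_test: int
    K_background: int
    n_test: int
    N_background: int
    p_raw: float
    p_bonferroni: float
    test_genes: frozenset[str] = frozenset()
    slim_targets: frozenset[str] = frozenset()
    reported: bool = False
    collapse_group: str = ""


def propagate_annotations(
    annotations: AnnotationSet, dag: OntologyDAG
) -> AnnotationSet:
    """Apply the true-path rule: annotate every gene to all is_a ancestors
    of its direct terms.  Unknown term ids are an error."""
    unknown = sorted(t for t in annotations.terms if t not in dag)
    if unknown:
        raise ValueError(f"annotation terms missing from ontology: {unknown}")
    out = {
        gene: set().union(terms, *(dag.ancestors(t) for t in terms))
        for gene, terms in annotations.annotations.items()
    }
    return AnnotationSet(out, set(annotations.background))


def term_enrichment(
    test_genes: set[str],
    annotations: AnnotationSet,
    dag: OntologyDAG,
    *,
    propagate: bool = True,
) -> list[EnrichmentResult]:
    """Hypergeometric over-representation of every term hit by the test set.

    For a term annotating K of N background genes and k of the n test
    genes, ``p_raw = P(X >= k)`` for X hypergeometric(N, K, n).  The
    Bonferroni multiplier is the number of terms tested (k >= 1 and
    K >= 2), and adjusted P is capped at 1.
    """
    stray = test_genes - annotations.background
    if stray:
        raise ValueError(f"test genes outside background universe: {sorted(stray)}")
    ann = propagate_annotations(annotations, dag) if propagate else annotations
    gene_sets: dict[str, set[str]] = {}
    for gene, terms in ann.annotations.items():
        for t in terms:
            gene_sets.setdefault(t, set()).add(gene)
    N, n = len(ann.background), len(test_genes)
    rows = []
    for term, genes in gene_sets.items():
        hits = genes & test_genes
        if not hits or len(genes) < 2:
            continue
        k, K = len(hits), len(genes)
        rows.append(
            EnrichmentResult(
                term_id=term,
                term_name=dag.name(term) if term in dag else term,
                k_test=k,
                K_background=K,
                n_test=n,
                N_background=N,
                p_raw=float(hypergeom.sf(k - 1, N, K, n)),
                p_bonferroni=1.0,
                test_genes=frozenset(hits),
            )
        )
    m = len(rows)
    for r in rows:
        r.p_bonferroni = min(1.0, r.p_raw * m)
    return sorted(rows, key=lambda r: (r.p_raw, r.term_id))


def select_significant(
    results: list[EnrichmentResult],
    alpha: float = 0.003,
    min_genes: int = 2,
) -> list[EnrichmentResult]:
    """Keep terms with Bonferroni-adjusted P strictly below ``alpha`` that
    annotate at least ``min_genes`` test genes."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if min_genes < 1:
        raise ValueError("min_genes must be >= 1")
    return [r for r in results if r.p_bonferroni < alpha and r.k_test >= min_genes]


def slim_remap(term_id: str, dag: OntologyDAG, slim_terms: set[str]) -> set[str]:
    """Most-specific slim ancestors of ``term_id``.

    A term already in the slim maps to itself.  Otherwise the reachable
    slim ancestors are filtered to those with no other reachable slim
    term strictly between them and ``term_id``; an empty set means the
    term falls outside the slim's coverage.
    """
    missing = sorted(t for t in slim_terms if t not in dag)
    if missing:
        raise ValueError(f"slim terms missing from ontology: {missing}")
    if term_id in slim_terms:
        return {term_id}
    reachable = dag.ancestors(term_id) & slim_terms
    return {
        s
        for s in reachable
        if not any(other != s and s in dag.ancestors(other) for other in reachable)
    }


def collapse_and_report(
    results: list[EnrichmentResult],
    dag: OntologyDAG,
    slim_terms: set[str],
    *,
    min_report_genes: int = 3,
    blacklist: set[str] = frozenset(),
) -> list[EnrichmentResult]:
    """Apply the reporting rules to significant terms.

    Blacklisted (nonspecific) terms are removed; each survivor is
    remapped to its most-specific slim ancestors, which define its
    collapse group; groups whose distinct test genes number fewer than
    ``min_report_genes`` are dropped; within a group a term whose test
    gene set is a subset of another's collapses into the superset term
    (ties keep the term with more background annotations, then the
    lexically smaller id).  Reported terms get ``reported=True``.
    """
    kept = [
        r
        for r in results
        if r.term_id not in blacklist and r.term_name not in blacklist
    ]
    groups: dict[str, list[EnrichmentResult]] = {}
    for r in kept:
        r.slim_targets = frozenset(slim_remap(r.term_id, dag, slim_terms))
        r.collapse_group = "|".join(sorted(r.slim_targets))
        groups.setdefault(r.collapse_group, []).append(r)
    reported = []
    for group, members in sorted(groups.items()):
        if not group:  # no slim coverage: reported separately as uncovered
            continue
        distinct = set().union(*(m.test_genes for m in members))
        if len(distinct) < min_report_genes:
            continue
        # collapse: drop terms nested in another member's gene set;
        # ties (equal sets) keep larger background K, then smaller id
        survivors = []
        for m in members:
            absorbed = False
            for other in members:
                if other is m:
                    continue
                if m.test_genes < other.test_genes:
                    absorbed = True
                    break
                if m.test_genes == other.test_genes:
                    if other.K_background > m.K_background or (
                        other.K_background == m.K_background
                        and other.term_id < m.term_id
                    ):
                        absorbed = True
                        break
            if not absorbed:
                survivors.append(m)
        for m in survivors:
            m.reported = True
            reported.append(m)
    return sorted(reported, key=lambda r: (r.p_raw, r.term_id))
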