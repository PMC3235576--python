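"""GO over-representation, slim remapping and report collapsing."""


import numpy as np
import pytest

from metacred import (
    AnnotationSet,
    OntologyDAG,
    collapse_and_report,
    fixture_enrichment_inputs,
    propagate_annotations,
    select_significant,
    simulate_annotation_universe,
    slim_remap,
    term_enrichment,
)
from metacred.fixtures import load_blacklist, load_reference_fixtures


def chain_dag():
    terms = {t: (t, "bp") for t in ["A", "B", "C"]}
    return OntologyDAG(terms, [("A", "B"), ("B", "C")])


def diamond_dag():
    terms = {t: (t, "bp") for t in ["leaf", "left", "right", "root"]}
    return OntologyDAG(
        terms,
        [("leaf", "left"), ("leaf", "right"), ("left", "root"), ("right", "root")],
    )


class TestPropagation:
    def test_chain_propagates_to_all_ancestors(self):
        annset = AnnotationSet({"g": {"A"}}, {"g"})
        out = propagate_annotations(annset, chain_dag())
        assert out.annotations["g"] == {"A", "B", "C"}

    def test_root_annotation_unchanged(self):
        annset = AnnotationSet({"g": {"C"}}, {"g"})
        out = propagate_annotations(annset, chain_dag())
        assert out.annotations["g"] == {"C"}
        again = propagate_annotations(out, chain_dag())
        assert again.annotations == out.annotations  # idempotent

    def test_unknown_term_listed_in_error(self):
        annset = AnnotationSet({"g": {"Z"}}, {"g"})
        with pytest.raises(ValueError, match="Z"):
            propagate_annotations(annset, chain_dag())

    def test_random_dag_matches_reachability_oracle(self):
        rng = np.random.default_rng(31)
        names = [f"T{i}" for i in range(12)]
        # edges only from lower to higher index: acyclic by construction
        edges = [
            (names[i], names[j])
            for i in range(12)
            for j in range(i + 1, 12)
            if rng.uniform() < 0.25
        ]
        dag = OntologyDAG({t: (t, "bp") for t in names}, edges)

        def reach(t):  # brute-force transitive closure
            seen, stack = set(), [t]
            while stack:
                cur = stack.pop()
                for _, parent in [e for e in edges if e[0] == cur]:
                    if parent not in seen:
                        seen.add(parent)
                        stack.append(parent)
            return seen

        annset = AnnotationSet({"g": {"T0", "T3"}}, {"g"})
        out = propagate_annotations(annset, dag)
        assert out.annotations["g"] == {"T0", "T3"} | reach("T0") | reach("T3")


def flat_universe(n_bg, term_genes, universe=None):
    """Annotation set + single-root DAG from term -> gene list mapping."""
    ann = {}
    for term, genes in term_genes.items():
        for g in genes:
            ann.setdefault(g, set()).add(term)
    universe = universe or ({f"bg{i}" for i in range(n_bg)} | set(ann))
    terms = {"root": ("root", "bp")}
    edges = []
    for t in term_genes:
        terms[t] = (t, "bp")
        edges.append((t, "root"))
    return AnnotationSet(ann, universe), OntologyDAG(terms, edges)


class TestTermEnrichment:
    def test_universal_term_has_p_one(self):
        universe = {f"g{i}" for i in range(20)}
        annset, dag = flat_universe(0, {"T": universe}, universe)
        res = term_enrichment({"g0", "g1", "g2"}, annset, dag)
        assert {r.term_id for r in res} == {"T", "root"}
        for r in res:
            assert r.p_raw == pytest.approx(1.0)

    def test_exact_tail_probability(self):
        # N=20, K=5, n=5, k=3: upper tail = 1126/15504 by direct enumeration
        universe = {f"g{i}" for i in range(20)}
        annotated = {f"g{i}" for i in range(5)}
        test = {"g0", "g1", "g2", "g10", "g11"}
        annset, dag = flat_universe(0, {"T": annotated}, universe)
        res = {r.term_id: r for r in term_enrichment(test, annset, dag)}
        assert res["T"].k_test == 3
        assert res["T"].p_raw == pytest.approx(1126 / 15504, abs=1e-12)

    def test_tail_monotone_in_overlap(self):
        # p(X >= k) decreases as the observed overlap grows
        universe = {f"g{i}" for i in range(30)}
        ps = []
        for k in range(1, 6):
            test = {f"g{i}" for i in range(5)}
            annotated = {f"g{i}" for i in range(k)} | {
                f"g{i}" for i in range(20, 25)
            }
            annset, dag = flat_universe(0, {"T": annotated}, universe)
            res = {r.term_id: r for r in term_enrichment(test, annset, dag)}
            ps.append(res["T"].p_raw)
        assert all(b < a for a, b in zip(ps, ps[1:]))

    def test_gene_outside_universe_rejected(self):
        annset, dag = flat_universe(10, {"T": {"bg0", "bg1"}})
        with pytest.raises(ValueError, match="outside"):
            term_enrichment({"nope"}, annset, dag)

    def test_planted_terms_rank_first(self):
        # planted terms should dominate the smallest raw P values
        hits = 0
        for rep in range(20):
            test = [f"T{i}" for i in range(8)]
            annset, dag = simulate_annotation_universe(
                300, [("GO:0000111", 10), ("GO:0000222", 12)], test,
                seed=1000 + rep,
            )
            res = term_enrichment(set(test), annset, dag)
            top2 = {r.term_id for r in res[:2]}
            hits += top2 == {"GO:0000111", "GO:0000222"}
        assert hits >= 18

    def test_bonferroni_multiplier_counts_tested_terms(self):
        universe = {f"g{i}" for i in range(40)}
        annset, dag = flat_universe(
            0,
            {"T1": {"g0", "g1", "g2"}, "T2": {"g0", "g5"}, "T3": {"g9", "g10"}},
            universe,
        )
        res = term_enrichment({"g0", "g1", "g2"}, annset, dag)
        m = len(res)  # only terms with k>=1 and K>=2 are tested
        for r in res:
            assert r.p_bonferroni == pytest.approx(min(1.0, r.p_raw * m))
            assert r.p_bonferroni >= r.p_raw


class TestSelectSignificant:
    def _fake(self, p_bonf, k):
        from metacred.enrichment import EnrichmentResult

        return EnrichmentResult("T", "T", k, 5, 10, 100, p_bonf / 2, p_bonf)

    def test_single_gene_terms_excluded(self):
        assert select_significant([self._fake(1e-5, 1)]) == []

    def test_boundary_alpha_is_strict(self):
        assert select_significant([self._fake(0.003, 2)]) == []
        assert select_significant([self._fake(0.00299, 2)]) != []

    def test_filter_matches_predicate_reapplication(self):
        rng = np.random.default_rng(37)
        results = [
            self._fake(float(rng.uniform(0, 0.01)), int(rng.integers(1, 5)))
            for _ in range(40)
        ]
        kept = select_significant(results, alpha=0.003, min_genes=2)
        assert kept == [
            r for r in results if r.p_bonferroni < 0.003 and r.k_test >= 2
        ]


class TestSlimRemap:
    def test_term_in_slim_maps_to_itself(self):
        dag = chain_dag()
        assert slim_remap("B", dag, {"B", "C"}) == {"B"}

    def test_most_specific_slim_ancestor_wins(self):
        dag = chain_dag()
        assert slim_remap("A", dag, {"B", "C"}) == {"B"}

    def test_diamond_returns_both_branches(self):
        dag = diamond_dag()
        assert slim_remap("leaf", dag, {"left", "right"}) == {"left", "right"}

    def test_no_slim_ancestor_gives_empty_set(self):
        dag = chain_dag()
        assert slim_remap("C", dag, {"A"}) == set()

    def test_invariant_under_intermediate_terms(self):
        # inserting a non-slim term in the middle of a chain changes nothing
        terms = {t: (t, "bp") for t in ["A", "mid", "B", "C"]}
        dag2 = OntologyDAG(terms, [("A", "mid"), ("mid", "B"), ("B", "C")])
        assert slim_remap("A", dag2, {"B", "C"}) == slim_remap(
            "A", chain_dag(), {"B", "C"}
        )

    def test_unknown_slim_term_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            slim_remap("A", chain_dag(), {"Z"})


class TestCollapseAndReport:
    def _enrich(self, term_genes, universe_size=100, test=None):
        annset, dag = flat_universe(universe_size, term_genes)
        test = test or set().union(*term_genes.values())
        res = term_enrichment(test, annset, dag)
        return res, dag

    def test_nested_gene_sets_collapse_to_superset_term(self):
        # "cell death" genes are a subset of "regulation of cell death":
        # one reported term for the pair
        term_genes = {
            "GO:0000100": {"g1", "g2", "g3"},
            "GO:0000200": {"g1", "g2", "g3", "g4"},
        }
        res, dag = self._enrich(term_genes)
        slim = {"GO:0000300"}
        dag2 = OntologyDAG(
            {**dag.terms, "GO:0000300": ("group", "bp")},
            [("GO:0000100", "GO:0000300"), ("GO:0000200", "GO:0000300"),
             ("GO:0000300", "root")],
        )
        reported = collapse_and_report(res, dag2, slim)
        names = {r.term_id for r in reported}
        assert names == {"GO:0000200"}

    def test_small_groups_dropped(self):
        term_genes = {"GO:0000100": {"g1", "g2"}}
        res, dag = self._enrich(term_genes)
        reported = collapse_and_report(res, dag, {"GO:0000100"},
                                       min_report_genes=3)
        assert reported == []

    def test_blacklisted_terms_removed(self):
        term_genes = {"GO:0000100": {"g1", "g2", "g3"}}
        res, dag = self._enrich(term_genes)
        reported = collapse_and_report(
            res, dag, {"GO:0000100"}, blacklist={"GO:0000100"}
        )
        assert reported == []


class TestFixturePathways:
    def test_fixture_reproduces_printed_gene_lists(self):
        test_genes, annset, dag, slim = fixture_enrichment_inputs()
        res = term_enrichment(test_genes, annset, dag)
        significant = select_significant(res)
        reported = collapse_and_report(
            significant, dag, slim, blacklist=load_blacklist()
        )
        _, pathways = load_reference_fixtures()
        expected = {p.term_id: set(p.genes) for p in pathways}
        assert {r.term_id: set(r.test_genes) for r in reported} == expected
        assert len(reported) == 9
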