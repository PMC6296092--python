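"""Enrichment tests: propagation, Fisher oracle equivalence, elim, calibration."""

import math

import numpy as np
import pytest

from snpcatalog.enrichment import (
    AnnotationTable,
    family_tests,
    fisher_term_tests,
    flag_tests,
    propagate_go,
)
from snpcatalog.errors import DomainError, InputValidationError
from snpcatalog.synthdata import generate_null_annotations


def hypergeom_tail(a: int, b: int, c: int, d: int) -> float:
    """One-sided (over-representation) Fisher p by explicit tail summation.

    With K = a + c category genes, n = a + b top genes, N = a+b+c+d genes in
    all: p = sum over k >= a of C(K, k) C(N-K, n-k) / C(N, n).
    """
    K, n, N = a + c, a + b, a + b + c + d
    denom = math.comb(N, n)
    total = 0
    for k in range(a, min(K, n) + 1):
        total += math.comb(K, k) * math.comb(N - K, n - k)
    return total / denom


def hypergeom_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p: sum of all table probabilities <= observed."""
    K, n, N = a + c, a + b, a + b + c + d
    denom = math.comb(N, n)
    p_obs = math.comb(K, a) * math.comb(N - K, n - a) / denom
    total = 0.0
    for k in range(max(0, n - (N - K)), min(K, n) + 1):
        p_k = math.comb(K, k) * math.comb(N - K, n - k) / denom
        if p_k <= p_obs * (1 + 1e-9):
            total += p_k
    return min(1.0, total)


class TestPropagation:
    CHAIN = [("leaf", "mid"), ("mid", "high"), ("high", "root")]

    def test_leaf_annotation_reaches_all_ancestors(self):
        full = propagate_go({"g1": {"leaf"}}, self.CHAIN)
        assert full["g1"] == {"leaf", "mid", "high", "root"}

    def test_idempotent(self):
        once = propagate_go({"g1": {"leaf"}}, self.CHAIN)
        assert propagate_go(once, self.CHAIN) == once

    def test_cycle_rejected(self):
        with pytest.raises(InputValidationError):
            propagate_go({}, [("a", "b"), ("b", "a")])

    def test_root_counts_all_annotated_genes(self):
        rng = np.random.default_rng(3)
        terms = [f"t{i}" for i in range(30)]
        edges = [(terms[i], terms[(i - 1) // 2]) for i in range(1, 30)]  # binary tree
        direct = {
            f"g{j}": {str(rng.choice(terms[10:]))} for j in range(100)
        }
        full = propagate_go(direct, edges)
        at_root = sum(1 for t in full.values() if terms[0] in t)
        assert at_root == len(direct)

    def test_monotone_counts_child_to_parent(self):
        rng = np.random.default_rng(5)
        terms = [f"t{i}" for i in range(15)]
        edges = [(terms[i], terms[(i - 1) // 2]) for i in range(1, 15)]
        direct = {f"g{j}": set(rng.choice(terms, size=2)) for j in range(80)}
        full = propagate_go(direct, edges)
        counts = {t: sum(1 for v in full.values() if t in v) for t in terms}
        for child, parent in edges:
            assert counts[child] <= counts[parent]


class TestFisherOracle:
    def test_spec_table_matches_tail_sum(self):
        res = fisher_term_tests(
            {**{f"top{i}": {"T"} for i in range(10)},
             **{f"topx{i}": set() for i in range(5)},
             **{f"bg{i}": {"T"} for i in range(90)},
             **{f"bgx{i}": set() for i in range(895)}},
            top_set={f"top{i}" for i in range(10)} | {f"topx{i}" for i in range(5)},
            universe={f"top{i}" for i in range(10)}
            | {f"topx{i}" for i in range(5)}
            | {f"bg{i}" for i in range(90)}
            | {f"bgx{i}" for i in range(895)},
        )
        (r,) = res
        assert (r.a, r.b, r.c, r.d) == (10, 5, 90, 895)
        assert r.p_value == pytest.approx(hypergeom_tail(10, 5, 90, 895), rel=1e-9)

    def test_exhaustive_small_tables(self):
        from scipy.stats import fisher_exact

        for N in (10, 17, 25):
            for a in range(0, N + 1):
                for b in range(0, N - a + 1):
                    for c in range(0, N - a - b + 1):
                        d = N - a - b - c
                        p = fisher_exact([[a, b], [c, d]], alternative="greater")[1]
                        assert p == pytest.approx(
                            hypergeom_tail(a, b, c, d), rel=1e-9, abs=1e-12
                        )

    def test_random_tables_up_to_500(self):
        from scipy.stats import fisher_exact

        rng = np.random.default_rng(19)
        for _ in range(300):
            N = int(rng.integers(4, 501))
            a, b, c = rng.multinomial(N, [0.25, 0.25, 0.25])[:3]
            d = N - a - b - c
            one = fisher_exact([[a, b], [c, d]], alternative="greater")[1]
            two = fisher_exact([[a, b], [c, d]], alternative="two-sided")[1]
            assert one == pytest.approx(hypergeom_tail(a, b, c, d), rel=1e-8, abs=1e-12)
            assert two == pytest.approx(
                hypergeom_two_sided(a, b, c, d), rel=1e-8, abs=1e-12
            )


class TestTermTests:
    def test_term_covering_all_genes_has_p_one(self):
        genes = {f"g{i}": {"T", "root"} for i in range(50)}
        res = fisher_term_tests(genes, {f"g{i}" for i in range(5)}, set(genes))
        assert all(r.p_value == pytest.approx(1.0) for r in res)

    def test_nodesize_excludes_small_terms(self):
        genes = {f"g{i}": {"big"} for i in range(20)}
        genes["g0"] = {"big", "tiny"}
        res = fisher_term_tests(genes, {"g0", "g1"}, set(genes), nodesize=5)
        assert {r.category for r in res} == {"big"}

    def test_empty_universe_rejected(self):
        with pytest.raises(DomainError):
            fisher_term_tests({}, set(), set())

    def test_elim_with_zero_alpha_equals_classic(self):
        rng = np.random.default_rng(23)
        edges = [("leaf1", "mid"), ("leaf2", "mid"), ("mid", "root")]
        genes = {}
        for i in range(60):
            terms = set(rng.choice(["leaf1", "leaf2", "mid"], size=1))
            genes[f"g{i}"] = terms
        full = propagate_go(genes, edges)
        top = set(rng.choice(sorted(full), size=6, replace=False))
        classic = fisher_term_tests(full, top, set(full), edges, method="classic")
        elim0 = fisher_term_tests(full, top, set(full), edges, method="elim",
                                  alpha_elim=0.0)
        assert {(r.category, r.p_value) for r in classic} == {
            (r.category, r.p_value) for r in elim0
        }

    def test_elim_removes_significant_child_genes_from_ancestors(self):
        edges = [("leaf", "mid"), ("mid", "root"), ("other", "root")]
        # leaf genes dominate the top set; under classic the mid-level
        # ancestor inherits the signal, under elim the leaf's genes are
        # removed from it first
        genes = {f"s{i}": {"leaf"} for i in range(10)}
        genes.update({f"m{i}": {"mid"} for i in range(20)})
        genes.update({f"b{i}": {"other"} for i in range(70)})
        full = propagate_go(genes, edges)
        top = {f"s{i}" for i in range(10)}
        classic = {r.category: r.p_value
                   for r in fisher_term_tests(full, top, set(full), method="classic")}
        elim = {r.category: r.p_value
                for r in fisher_term_tests(full, top, set(full), edges,
                                           method="elim", alpha_elim=0.01)}
        assert classic["mid"] < 0.05  # inherited signal
        assert elim["mid"] > classic["mid"]  # decorrelated away
        assert elim["leaf"] == classic["leaf"]  # leaves unaffected

    def test_designated_enriched_categories_detected(self, bundle,
                                                     pipeline_products):
        from snpcatalog.synthdata import DESIGNATED_FAMILY, DESIGNATED_TERM

        top = pipeline_products["top"]
        universe = {g.gene_id for g in pipeline_products["ranked"]}
        fams = family_tests(bundle.annotations, top, universe)
        p_fam = {r.category: r.p_value for r in fams}[DESIGNATED_FAMILY]
        assert p_fam < 0.05
        go = {g: t for g, t in bundle.annotations.go.items() if g in universe}
        full = propagate_go(go, bundle.go_edges)
        res = fisher_term_tests(full, top & set(full), set(full), bundle.go_edges)
        p_term = {r.category: r.p_value for r in res}[DESIGNATED_TERM]
        assert p_term < 0.05


class TestFamilies:
    @staticmethod
    def _table(families):
        return AnnotationTable(go={}, family=families, orphan=set(),
                               conifer_specific=set())

    def test_min_in_top_rule(self):
        fams = {f"g{i}": "famA" for i in range(10)}
        fams.update({f"h{i}": "famB" for i in range(10)})
        universe = set(fams)
        top = {"g0", "h0", "h1"}  # famA has one member in top, famB two
        res = family_tests(self._table(fams), top, universe)
        assert {r.category for r in res} == {"famB"}

    def test_bh_adjustment_matches_manual_formula(self):
        rng = np.random.default_rng(29)
        fams = {}
        for i in range(400):
            fams[f"g{i}"] = f"fam{i % 8}"
        universe = set(fams)
        top = set(rng.choice(sorted(universe), size=40, replace=False))
        res = family_tests(self._table(fams), top, universe, adjust="BH")
        ps = [r.p_value for r in res]
        m = len(ps)
        # manual step-up: q_(i) = min over j>=i of p_(j) * m / j
        order = np.argsort(ps)
        manual = np.empty(m)
        running = 1.0
        for rank in range(m - 1, -1, -1):
            running = min(running, ps[order[rank]] * m / (rank + 1))
            manual[order[rank]] = running
        for r, q in zip(res, manual):
            assert r.p_adjusted == pytest.approx(q)

    def test_null_families_rarely_significant_after_bh(self, bundle):
        # no-signal side check on the shared bundle: families other than the
        # designated one should survive BH at 0.05 only rarely
        from snpcatalog.synthdata import DESIGNATED_FAMILY

        universe = set(bundle.annotations.family) | bundle.annotations.orphan
        rng = np.random.default_rng(31)
        top = set(rng.choice(sorted(universe), size=len(universe) // 10,
                             replace=False))
        res = family_tests(bundle.annotations, top, universe)
        significant = [r.category for r in res
                       if r.p_adjusted is not None and r.p_adjusted < 0.05
                       and r.category != DESIGNATED_FAMILY]
        assert len(significant) <= 1


class TestFlags:
    def _table(self, conifer, universe):
        return AnnotationTable(go={}, family={g: "f" for g in universe},
                               orphan=set(), conifer_specific=conifer)

    def test_absent_flag_is_undefined(self):
        universe = {f"g{i}" for i in range(20)}
        r = flag_tests(self._table(set(), universe), {"g0", "g1"}, universe,
                       "conifer_specific")
        assert r.p_value == 1.0 and r.extra["defined"] is False

    def test_equal_proportions_not_significant(self):
        universe = {f"g{i}" for i in range(100)}
        top = {f"g{i}" for i in range(10)}
        flagged = {f"g{i}" for i in range(0, 100, 10)}  # 10% everywhere
        r = flag_tests(self._table(flagged, universe), top, universe,
                       "conifer_specific")
        assert r.p_value > 0.5

    def test_strong_excess_detected_and_matches_oracle(self):
        universe = {f"g{i}" for i in range(1000)}
        top = {f"g{i}" for i in range(100)}
        flagged = {f"g{i}" for i in range(40)} | {"g500", "g501"}
        r = flag_tests(self._table(flagged, universe), top, universe,
                       "conifer_specific")
        assert r.p_value < 0.001
        assert r.p_value == pytest.approx(
            hypergeom_two_sided(r.a, r.b, r.c, r.d), rel=1e-8
        )
        assert r.extra["prop_top"] == pytest.approx(0.40)
        assert r.extra["prop_rest"] == pytest.approx(2 / 900)


class TestCalibration:
    def test_null_type_one_error_near_nominal(self):
        annotations, top, universe = generate_null_annotations(
            1000, 2000, seed=11
        )
        res = fisher_term_tests(annotations, top, universe, nodesize=5)
        assert len(res) >= 1000
        frac = np.mean([r.p_value < 0.05 for r in res])
        assert 0.03 <= frac <= 0.07
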