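"""Consensus catalog: intersection semantics, filter cascade, flanks, summary."""

import math
from collections import Counter

import numpy as np
import pytest

from snpcatalog.catalog import (
    CallerVariant,
    FilterThresholds,
    MatchedPair,
    apply_quality_filters,
    build_consensus_snp,
    extract_flanks,
    failed_filters,
    intersect_callsets,
    summarize_catalog,
    summarize_catalog_counts,
    union_size,
)
from snpcatalog.catalog import ConsensusSNP
from snpcatalog.errors import (
    CoordinateError,
    DomainError,
    InputValidationError,
)

PASSING = dict(
    MQ=40.0, MMLQ=20.0, QD=15.0, PP=50.0, SbPval=0.5,
    HapScore=20.0, MGOF=30.0, SC=0.99,
)


def variant(caller="A", contig="c1", pos=10, ref="A", alts=("G",),
            ref_reads=50, alt_reads=(30,), **overrides):
    fields = dict(PASSING)
    fields.update(overrides)
    return CallerVariant(
        caller_id=caller, contig_id=contig, pos=pos, ref=ref, alts=alts,
        ref_reads=ref_reads, alt_reads=alt_reads, **fields,
    )


class TestIntersection:
    def test_study_scale_union(self):
        assert union_size(115336, 191334, 68004) == 238666

    def test_identical_sets(self):
        a = [variant(pos=p) for p in (1, 5, 9)]
        b = [variant(caller="B", pos=p) for p in (1, 5, 9)]
        common, union = intersect_callsets(a, b)
        assert len(common) == 3 and union == 3

    def test_disjoint_sets(self):
        a = [variant(pos=p) for p in (1, 5)]
        b = [variant(caller="B", pos=p) for p in (2, 6, 7)]
        common, union = intersect_callsets(a, b)
        assert common == [] and union == 5

    def test_allele_mismatch_is_not_common(self):
        a = [variant(pos=3, alts=("G",))]
        b = [variant(caller="B", pos=3, alts=("T",))]
        common, union = intersect_callsets(a, b)
        assert common == [] and union == 2

    def test_case_insensitive_allele_match(self):
        a = [variant(pos=3, ref="a", alts=("g",))]
        b = [variant(caller="B", pos=3, ref="A", alts=("G",))]
        common, _ = intersect_callsets(a, b)
        assert len(common) == 1

    def test_duplicate_sites_rejected_with_offenders(self):
        a = [variant(pos=3), variant(pos=3, alts=("T",))]
        with pytest.raises(InputValidationError, match=r"\('c1', 3\)"):
            intersect_callsets(a, [])

    def test_common_bounded_by_smaller_set(self):
        rng = np.random.default_rng(2)
        a = [variant(pos=int(p)) for p in rng.choice(1000, 80, replace=False) + 1]
        b = [variant(caller="B", pos=int(p))
             for p in rng.choice(1000, 120, replace=False) + 1]
        common, union = intersect_callsets(a, b)
        assert len(common) <= min(len(a), len(b))
        assert union >= max(len(a), len(b))


class TestQualityFilters:
    @pytest.mark.parametrize(
        "field, failing, passing",
        [
            ("MQ", 19.9, 20.0),
            ("MMLQ", 9.9, 10.0),
            ("QD", 9.9, 10.0),
            ("PP", 19.9, 20.0),
            ("SbPval", 0.009, 0.01),
            ("HapScore", 14.9, 15.0),
            ("MGOF", 19.9, 20.0),
            ("SC", 0.94, 0.95),
        ],
    )
    def test_each_threshold_boundary(self, field, failing, passing):
        assert failed_filters(variant(**{field: failing})) == [field]
        assert failed_filters(variant(**{field: passing})) == []

    def test_singleton_excluded(self):
        assert failed_filters(variant(alt_reads=(1,))) == ["min_alt_reads"]

    def test_triallelic_excluded(self):
        v = variant(alts=("G", "T"), alt_reads=(20, 10))
        assert failed_filters(v) == ["biallelic"]

    def test_mgof_inversion_switch(self):
        t = FilterThresholds(mgof_inverted=True)
        assert failed_filters(variant(MGOF=25.0), t) == ["MGOF"]
        assert failed_filters(variant(MGOF=15.0), t) == []

    def test_missing_annotation_names_site_and_field(self):
        v = variant(QD=None)
        with pytest.raises(InputValidationError, match="c1:10.*QD"):
            failed_filters(v)

    def test_audit_counts_every_violation(self):
        bad = variant(MQ=5.0, SC=0.5)  # violates two criteria at once
        good = variant(pos=11)
        pairs = [
            MatchedPair(bad, variant(caller="B")),
            MatchedPair(good, variant(caller="B", pos=11)),
        ]
        passing, audit = apply_quality_filters(pairs)
        assert [p.a.pos for p in passing] == [11]
        assert audit["MQ"] == 1 and audit["SC"] == 1
        assert sum(audit.values()) == 2  # one rejection, two tallies

    def test_order_independent_conjunction(self):
        rng = np.random.default_rng(0)
        pairs = []
        for i in range(200):
            kw = {}
            if rng.uniform() < 0.3:
                kw["MQ"] = float(rng.uniform(0, 19))
            v = variant(pos=i + 1, **kw)
            pairs.append(MatchedPair(v, variant(caller="B", pos=i + 1)))
        fwd, _ = apply_quality_filters(pairs)
        rev, _ = apply_quality_filters(list(reversed(pairs)))
        assert {p.a.site for p in fwd} == {p.a.site for p in rev}


class TestSyntheticRecovery:
    def test_passing_set_equals_ground_truth(self, bundle, pipeline_products):
        truth = bundle.truth.variants
        expected = set(truth.index[truth["passes_quality"]])
        got = {p.a.site for p in pipeline_products["passing"]}
        assert got == expected

    def test_audit_matches_planted_violations(self, bundle, pipeline_products):
        truth = bundle.truth.variants
        planted = Counter(
            truth.loc[truth["failed_filter"] != "", "failed_filter"]
        )
        audit = pipeline_products["audit"]
        assert {k: v for k, v in audit.items() if v} == dict(planted)


class TestFlanks:
    SEQ = "".join(
        np.random.default_rng(9).choice(list("ACGT"), size=400)
    )

    def test_first_position_has_empty_upstream(self):
        up, down = extract_flanks(1, self.SEQ)
        assert up == ""
        assert len(down) == 100

    def test_interior_position_has_full_flanks(self):
        up, down = extract_flanks(150, self.SEQ)
        assert len(up) == len(down) == 100
        assert up == self.SEQ[49:149] and down == self.SEQ[150:250]

    def test_near_end_truncates_downstream(self):
        L = len(self.SEQ)
        up, down = extract_flanks(L - 30, self.SEQ)
        assert len(down) == 30
        assert down == self.SEQ[L - 30 :]

    @pytest.mark.parametrize("pos", [0, -5, 401])
    def test_out_of_range_position(self, pos):
        with pytest.raises(CoordinateError):
            extract_flanks(pos, self.SEQ)

    def test_short_contig_flanks_bounded_by_sequence(self):
        seq = self.SEQ[:150]
        for pos in range(1, 151):
            up, down = extract_flanks(pos, seq)
            assert len(up) == min(100, pos - 1)
            assert len(down) == min(100, len(seq) - pos)


class TestConsensusSnp:
    def test_maf_from_read_counts(self):
        pair = MatchedPair(variant(ref_reads=70, alt_reads=(30,)),
                           variant(caller="B"))
        snp = build_consensus_snp(pair)
        assert snp.depth == 100
        assert snp.maf == pytest.approx(0.30)

    def test_maf_folded_above_half(self):
        pair = MatchedPair(variant(ref_reads=20, alt_reads=(80,)),
                           variant(caller="B"))
        assert build_consensus_snp(pair).maf == pytest.approx(0.20)

    def test_maf_always_in_range(self):
        rng = np.random.default_rng(4)
        for _ in range(200):
            ref, alt = int(rng.integers(0, 200)), int(rng.integers(2, 200))
            pair = MatchedPair(
                variant(ref_reads=ref, alt_reads=(alt,)), variant(caller="B")
            )
            snp = build_consensus_snp(pair)
            f = alt / (ref + alt)
            assert snp.maf == pytest.approx(min(f, 1 - f))
            assert 0.0 <= snp.maf <= 0.5


class TestSummary:
    def test_study_scale_ratios(self):
        s = summarize_catalog_counts(61771, 13543, 16516, abundance_per_100=0.234)
        assert round(s.snps_per_snped_gene, 2) == 4.56
        assert round(s.snps_per_gene_all, 2) == 3.74
        assert s.n_unsnped_genes == 2973
        assert s.sites_per_snp == 427

    def test_object_path_consistency(self):
        snps = [
            ConsensusSNP("c1", p, "A", "G", 100, 0.3, gene_id=g)
            for p, g in [(10, "g1"), (20, "g1"), (30, "g2")]
        ]
        s = summarize_catalog(snps, {"g1", "g2", "g3"}, {"g1": 1000, "g2": 500, "g3": 800})
        assert s.n_snps == 3 and s.n_snped_genes == 2 and s.n_unsnped_genes == 1
        assert s.snps_per_snped_gene == pytest.approx(1.5)
        assert s.snps_per_gene_all == pytest.approx(1.0)
        assert s.abundance_per_100 == pytest.approx(100 * 3 / 1500)
        assert s.sites_per_snp == round(1500 / 3)

    def test_unknown_gene_rejected(self):
        snps = [ConsensusSNP("c1", 10, "A", "G", 100, 0.3, gene_id="gX")]
        with pytest.raises(InputValidationError):
            summarize_catalog(snps, {"g1"}, {"g1": 100})

    def test_zero_genes_flagged(self):
        s = summarize_catalog([], set(), {})
        assert math.isnan(s.snps_per_snped_gene)
        assert s.sites_per_snp is None
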