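"""Copy-number classification, SNV filter cascade, severity, concordance."""

from dataclasses import replace
from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest
from scipy.stats import fisher_exact

from tmenet import (CNSegment, DataError, FilterThresholds, GeneModel,
                    VariantRecord, alteration_frequencies_and_tests,
                    classify_gene_copy_number, cluster_mutation_profiles,
                    cn_category, filter_somatic_snvs, max_severity_per_gene,
                    pairwise_concordance, severity_rank)


# ---------------------------------------------------------------------------
# copy number
# ---------------------------------------------------------------------------

EPS = 1e-9


class TestCopyNumberClassification:
    # (case, segment CNs, expected category, expected selected CN)
    CASES = [
        ("del_below_boundary", [1.0 - EPS], "deletion", 1.0 - EPS),
        ("loss_at_one", [1.0], "loss", 1.0),
        ("loss_below_185", [1.85 - EPS], "loss", 1.85 - EPS),
        ("diploid_at_185", [1.85], "diploid", 1.85),
        ("diploid_at_215", [2.15], "diploid", 2.15),
        ("gain_above_215", [2.15 + EPS], "gain", 2.15 + EPS),
        ("gain_at_four", [4.0], "gain", 4.0),
        ("amp_above_four", [4.0 + EPS], "amplification", 4.0 + EPS),
        ("most_deviant_wins", [2.0, 3.1], "gain", 3.1),
        ("deletion_precedence", [0.8, 5.0], "deletion", 0.8),
        ("single_diploid", [2.0], "diploid", 2.0),
        ("tie_resolves_low", [1.5, 2.5], "loss", 1.5),
    ]

    @staticmethod
    def _build(cns, gene, offset):
        """One gene spanning len(cns) adjacent segments on its own locus."""
        width = 1000
        segs = [CNSegment("S1", "chr1", offset + i * width,
                          offset + (i + 1) * width - 1, cn)
                for i, cn in enumerate(cns)]
        model = GeneModel(gene, "chr1", offset, offset + len(cns) * width - 1)
        return segs, model

    @pytest.mark.parametrize("name,cns,category,selected", CASES,
                             ids=[c[0] for c in CASES])
    def test_twelve_case_fixture(self, name, cns, category, selected):
        segs, model = self._build(cns, name, 10_000)
        calls = classify_gene_copy_number(segs, [model])
        assert len(calls) == 1
        assert calls[0].category == category
        assert calls[0].selected_cn == pytest.approx(selected, abs=1e-15)

    def test_full_fixture_in_one_sample(self):
        segs, models = [], []
        offset = 1
        for name, cns, *_ in self.CASES:
            s, m = self._build(cns, name, offset)
            segs += s
            models.append(m)
            offset += 1_000_000
        calls = {c.gene: c for c in classify_gene_copy_number(segs, models)}
        for name, _, category, selected in self.CASES:
            assert calls[name].category == category, name
            assert calls[name].selected_cn == pytest.approx(selected)

    def test_uncovered_gene_emits_no_call(self):
        segs = [CNSegment("S1", "chr1", 1, 100, 2.0)]
        genes = [GeneModel("far", "chr1", 5000, 6000),
                 GeneModel("otherchrom", "chr2", 1, 100)]
        assert classify_gene_copy_number(segs, genes) == []

    def test_any_base_overlap_counts(self):
        # gene's last base touches the segment's first base (closed intervals)
        segs = [CNSegment("S1", "chr1", 100, 200, 4.5)]
        genes = [GeneModel("touch", "chr1", 50, 100)]
        calls = classify_gene_copy_number(segs, genes)
        assert calls[0].category == "amplification"

    def test_overlapping_segments_rejected(self):
        segs = [CNSegment("S1", "chr1", 1, 100, 2.0),
                CNSegment("S1", "chr1", 100, 200, 3.0)]
        with pytest.raises(DataError, match="overlap"):
            classify_gene_copy_number(segs, [GeneModel("g", "chr1", 1, 50)])

    def test_category_function_boundaries(self):
        for cn, cat in [(0.0, "deletion"), (1.0, "loss"), (1.85, "diploid"),
                        (2.15, "diploid"), (2.16, "gain"), (4.0, "gain"),
                        (4.01, "amplification")]:
            assert cn_category(cn) == cat


# ---------------------------------------------------------------------------
# SNV filter cascade
# ---------------------------------------------------------------------------

def make_variant(**overrides) -> VariantRecord:
    base = dict(sample="T1", patient="P1", gene="KRAS", chrom="chr1",
                pos=100, ref="C", alt="T", mutation_type="missense",
                t_alt_reads=20, n_supporting=30, vaf_tumor=0.3,
                vaf_normal=0.02, p_somatic=0.01, dist_read_end=15,
                p_base_quality=0.5, p_mapping_quality=0.5, p_strand_bias=0.5)
    base.update(overrides)
    return VariantRecord(**base)


class TestFilterCascade:
    #: one violation per rule, fields chosen just past each threshold
    VIOLATIONS = [
        ("min_tumor_reads", dict(t_alt_reads=7)),
        ("min_normal_reads", dict(n_supporting=5)),
        ("min_vaf_tumor", dict(vaf_tumor=0.08)),
        ("max_vaf_normal", dict(vaf_normal=0.12)),
        ("p_somatic", dict(p_somatic=0.051)),
        ("dist_read_end", dict(dist_read_end=3)),
        ("base_quality", dict(p_base_quality=0.01)),
        ("mapping_quality", dict(p_mapping_quality=0.01)),
        ("strand_bias", dict(p_strand_bias=0.04)),
    ]

    def test_thirty_record_fixture(self):
        records = [make_variant(pos=i) for i in range(20)]           # pass
        for i, (_, bad) in enumerate(self.VIOLATIONS):               # 9 fails
            records.append(make_variant(pos=100 + i, **bad))
        records.append(make_variant(pos=999, p_strand_bias=None))    # 1 n/e
        assert len(records) == 30
        passed, audit = filter_somatic_snvs(records)
        assert audit["passed"] == len(passed) == 20
        assert audit["not_evaluable"] == 1
        for rule, _ in self.VIOLATIONS:
            assert audit[rule] == 1, rule
        assert {v.pos for v in passed} == set(range(20))

    def test_boundary_values_pass(self):
        v = make_variant(t_alt_reads=8, n_supporting=6, vaf_tumor=0.1,
                         vaf_normal=0.1, p_somatic=0.05, dist_read_end=5,
                         p_base_quality=0.05, p_mapping_quality=0.05,
                         p_strand_bias=0.05)
        passed, audit = filter_somatic_snvs([v])
        assert len(passed) == 1 and audit["passed"] == 1

    def test_first_failing_rule_attribution(self):
        # violates both tumor-reads and VAF rules: attributed to the first
        v = make_variant(t_alt_reads=2, vaf_tumor=0.01)
        _, audit = filter_somatic_snvs([v])
        assert audit["min_tumor_reads"] == 1
        assert audit["min_vaf_tumor"] == 0

    def test_audit_counts_balance(self, small_cohort):
        passed, audit = filter_somatic_snvs(small_cohort.variants)
        rule_sum = sum(v for k, v in audit.items()
                       if k not in ("passed", "not_evaluable"))
        assert rule_sum == (len(small_cohort.variants) - audit["passed"]
                            - audit["not_evaluable"])

    def test_custom_thresholds(self):
        v = make_variant(vaf_tumor=0.15)
        _, audit = filter_somatic_snvs([v], FilterThresholds(min_vaf_tumor=0.2))
        assert audit["min_vaf_tumor"] == 1


class TestSeverity:
    def test_published_ordering(self):
        assert (severity_rank("missense") < severity_rank("inframe_indel")
                < severity_rank("splice") < severity_rank("frameshift_indel"))
        assert severity_rank("frameshift_indel") == severity_rank("nonsense")

    def test_types_outside_ordering_rank_zero(self):
        assert severity_rank("synonymous") == 0
        assert severity_rank("intergenic_whatever") == 0

    def test_per_gene_summary_keeps_maximum(self):
        recs = [make_variant(mutation_type="missense"),
                make_variant(pos=200, mutation_type="nonsense"),
                make_variant(pos=300, gene="APC", mutation_type="synonymous")]
        tab = max_severity_per_gene(recs).set_index("gene")
        assert tab.loc["KRAS", "severity"] == 4
        assert tab.loc["APC", "severity"] == 0


# ---------------------------------------------------------------------------
# Fisher tests on group frequencies
# ---------------------------------------------------------------------------

def fisher_two_sided_oracle(a: int, b: int, c: int, d: int) -> float:
    """Exact two-sided Fisher p by enumerating all tables with the observed
    margins and summing probabilities <= the observed one (rationals)."""
    r1, r2 = a + b, c + d
    c1 = a + c
    N = r1 + r2

    def prob(x: int) -> Fraction:
        return Fraction(comb(r1, x) * comb(r2, c1 - x), comb(N, c1))

    p_obs = prob(a)
    cutoff = p_obs + Fraction(p_obs, 10**7)  # scipy's relative tolerance
    total = Fraction(0)
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        if prob(x) <= cutoff:
            total += prob(x)
    return float(min(total, Fraction(1)))


def group_samples(n_a: int, n_b: int) -> pd.DataFrame:
    ids = [f"A{i}" for i in range(n_a)] + [f"B{i}" for i in range(n_b)]
    return pd.DataFrame({
        "group": ["GA"] * n_a + ["GB"] * n_b,
        "patient": ids,
    }, index=ids)


class TestAlterationFrequencies:
    @staticmethod
    def _variants_for(gene, sample_ids):
        return [make_variant(sample=s, patient=s, gene=gene, pos=i)
                for i, s in enumerate(sample_ids)]

    def test_three_of_thirteen_vs_zero_of_thirty(self):
        samples = group_samples(13, 30)
        recs = self._variants_for("BCOR", ["A0", "A1", "A2"])
        tab = alteration_frequencies_and_tests(recs, [], samples,
                                               ("GA", "GB"), include_cn=False)
        expected = fisher_two_sided_oracle(3, 10, 0, 30)
        assert tab.loc[0, "p"] == pytest.approx(expected, abs=1e-10)

    def test_total_separation_exact_value(self):
        samples = group_samples(10, 10)
        recs = self._variants_for("TP53", [f"A{i}" for i in range(10)])
        tab = alteration_frequencies_and_tests(recs, [], samples,
                                               ("GA", "GB"), include_cn=False)
        expected = fisher_two_sided_oracle(10, 0, 0, 10)
        assert tab.loc[0, "p"] == pytest.approx(expected, abs=1e-10)
        # hand value: 2 * C(10,10)*C(10,0)/C(20,10) = 2/184756
        assert expected == pytest.approx(2.0 / comb(20, 10), abs=1e-12)

    def test_equal_frequencies_give_p_one(self):
        samples = group_samples(8, 8)
        recs = self._variants_for("APC", ["A0", "A1", "B0", "B1"])
        tab = alteration_frequencies_and_tests(recs, [], samples,
                                               ("GA", "GB"), include_cn=False)
        assert tab.loc[0, "p"] == pytest.approx(1.0)

    def test_scipy_matches_oracle_over_margin_grid(self):
        for a in range(0, 8, 2):
            for b in range(0, 8, 3):
                for c in range(0, 8, 2):
                    for d in range(0, 8, 3):
                        if (a + b) and (c + d) and (a + b + c + d) <= 40:
                            p = fisher_exact([[a, b], [c, d]])[1]
                            assert p == pytest.approx(
                                fisher_two_sided_oracle(a, b, c, d), abs=1e-10)

    def test_synonymous_only_not_altered(self):
        samples = group_samples(4, 4)
        recs = [make_variant(sample="A0", patient="A0", gene="MUC16",
                             mutation_type="synonymous")]
        with pytest.raises(DataError):
            alteration_frequencies_and_tests(recs, [], samples, ("GA", "GB"),
                                             include_cn=False)


# ---------------------------------------------------------------------------
# concordance
# ---------------------------------------------------------------------------

def paired_samples() -> pd.DataFrame:
    return pd.DataFrame({
        "group": ["CWM", "CLM"],
        "patient": ["P1", "P1"],
    }, index=["T1", "M1"])


def site_variants(sample, patient, positions):
    return [make_variant(sample=sample, patient=patient, pos=p)
            for p in positions]


class TestPairwiseConcordance:
    def test_identical_sets(self):
        recs = (site_variants("T1", "P1", range(10))
                + site_variants("M1", "P1", range(10)))
        pp, _ = pairwise_concordance(recs, paired_samples(), "CWM", "CLM")
        assert pp.loc[0, "concordance"] == pytest.approx(1.0)

    def test_disjoint_sets(self):
        recs = (site_variants("T1", "P1", range(10))
                + site_variants("M1", "P1", range(100, 110)))
        pp, _ = pairwise_concordance(recs, paired_samples(), "CWM", "CLM")
        assert pp.loc[0, "concordance"] == pytest.approx(0.0)

    def test_eight_shared_two_private(self):
        recs = (site_variants("T1", "P1", list(range(8)) + [100])
                + site_variants("M1", "P1", list(range(8)) + [200]))
        pp, _ = pairwise_concordance(recs, paired_samples(), "CWM", "CLM")
        assert pp.loc[0, "shared"] == 8
        assert pp.loc[0, "a_only"] == 1 and pp.loc[0, "b_only"] == 1
        assert pp.loc[0, "concordance"] == pytest.approx(0.8)

    def test_symmetric_in_group_order(self):
        recs = (site_variants("T1", "P1", list(range(8)) + [100])
                + site_variants("M1", "P1", list(range(8)) + [200, 300]))
        ab, _ = pairwise_concordance(recs, paired_samples(), "CWM", "CLM")
        ba, _ = pairwise_concordance(recs, paired_samples(), "CLM", "CWM")
        assert ab.loc[0, "concordance"] == pytest.approx(
            ba.loc[0, "concordance"])

    def test_unpaired_patient_excluded(self):
        samples = pd.DataFrame({
            "group": ["CWM", "CLM", "CWM"],
            "patient": ["P1", "P1", "P2"],
        }, index=["T1", "M1", "T2"])
        recs = (site_variants("T1", "P1", range(5))
                + site_variants("M1", "P1", range(5))
                + site_variants("T2", "P2", range(5)))
        pp, _ = pairwise_concordance(recs, samples, "CWM", "CLM")
        assert list(pp["patient"]) == ["P1"]

    def test_generated_cohort_matches_configured_concordance(self, small_cohort):
        passed, _ = filter_somatic_snvs(small_cohort.variants)
        pp, _ = pairwise_concordance(passed, small_cohort.samples,
                                     "CWM", "CLM")
        target = small_cohort.config.variant_params.concordance
        assert abs(pp["concordance"].mean() - target) < 0.03


# ---------------------------------------------------------------------------
# mutation-profile clustering
# ---------------------------------------------------------------------------

class TestClusterMutationProfiles:
    def test_identical_samples_distance_zero(self):
        samples = pd.DataFrame({"group": ["CWM", "CLM"],
                                "patient": ["P1", "P1"]}, index=["T1", "M1"])
        recs = (site_variants("T1", "P1", range(6))
                + site_variants("M1", "P1", range(6)))
        d = cluster_mutation_profiles(recs, samples)
        assert d.linkage_matrix[0, 2] == pytest.approx(0.0)

    def test_disjoint_samples_distance_one(self):
        samples = pd.DataFrame({"group": ["CWM", "CLM"],
                                "patient": ["P1", "P1"]}, index=["T1", "M1"])
        recs = (site_variants("T1", "P1", range(6))
                + site_variants("M1", "P1", range(100, 106)))
        d = cluster_mutation_profiles(recs, samples)
        assert d.linkage_matrix[0, 2] == pytest.approx(1.0)

    def test_matched_pairs_aggregate_together(self, small_cohort):
        # at concordance 0.9 each patient's primary and metastasis merge
        # with each other before joining any other sample
        passed, _ = filter_somatic_snvs(small_cohort.variants)
        samples = small_cohort.samples
        tumor = samples[samples["group"].isin(["CWM", "CLM"])]
        d = cluster_mutation_profiles(passed, tumor)
        leaf = {s: i for i, s in enumerate(d.labels)}
        merged_pairs = {tuple(sorted(row[:2].astype(int)))
                        for row in d.linkage_matrix}
        pats = tumor.groupby("patient").groups
        n_checked = 0
        for patient, ids in pats.items():
            if len(ids) == 2:
                pair = tuple(sorted(leaf[s] for s in ids))
                assert pair in merged_pairs, patient
                n_checked += 1
        assert n_checked >= 8
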