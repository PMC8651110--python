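"""Filter cascade verdicts, strand-bias test and spectrum calibration."""

import numpy as np
import pytest
from scipy import stats

from deepsoma.calls import VariantCall, passing
from deepsoma.filters import (
    DEFAULT_ALPHA_GRID,
    FILTER_ORDER,
    FilterThresholds,
    apply_filters,
    attrition_table,
    calibrate_sensitivity,
    classify_consequence_summary,
    collect_germline_calls,
    germline_mask_from_calls,
    strand_bias_test,
    substitution_spectrum,
)
from deepsoma.noise import ContextNoiseModel, GermlineMask

from conftest import make_call


@pytest.fixture(scope="module")
def flat_noise_model():
    """A fully populated model with ~1e-4 everywhere (large opportunities)."""
    mis = np.full((64, 4), 100, dtype=np.int64)
    opp = np.full((64, 4), 1_000_000, dtype=np.int64)
    return ContextNoiseModel(mis, opp)


class TestStrandBias:
    def test_balanced_counts_no_bias(self):
        assert strand_bias_test(10, 10, 1000, 1000) == pytest.approx(1.0)

    @pytest.mark.parametrize(
        "table",
        [(20, 0, 1000, 1000), (15, 2, 800, 900), (5, 30, 1200, 1100), (3, 0, 50, 70)],
    )
    def test_matches_exact_hypergeometric_oracle(self, table):
        # oracle: scipy's reference Fisher exact implementation
        ours = strand_bias_test(*table)
        a, b, c, d = table
        ref = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided").pvalue
        assert ours == pytest.approx(float(ref), rel=1e-9)

    def test_one_sided_excess_is_small(self):
        assert strand_bias_test(20, 0, 1000, 1000) < 1e-4

    def test_strand_swap_symmetry(self):
        assert strand_bias_test(14, 3, 900, 1100) == pytest.approx(
            strand_bias_test(3, 14, 1100, 900), rel=1e-9
        )

    def test_requires_a_variant_read(self):
        with pytest.raises(ValueError):
            strand_bias_test(0, 0, 100, 100)


class TestThresholds:
    def test_defaults_match_documented_values(self):
        t = FilterThresholds()
        assert (t.min_depth, t.max_pop_af, t.germline_vaf_low) == (100, 1e-5, 0.35)
        assert (t.cluster_window_bp, t.cluster_max_variants) == (100, 2)

    @pytest.mark.parametrize(
        "kw",
        [{"germline_vaf_low": 0.9}, {"strand_bias_alpha": 0.0}, {"mapq_max_deficit": -1}],
    )
    def test_out_of_range_rejected(self, kw):
        with pytest.raises(ValueError):
            FilterThresholds(**kw)


class TestCascadeVerdicts:
    def _run(self, calls, model, **kw):
        return apply_filters(calls, None, model, **kw)

    def test_every_filter_evaluated_on_every_call(self, flat_noise_model):
        calls = [make_call(), make_call(pos=5000, depth=90, alt_count=40)]
        self._run(calls, flat_noise_model)
        for c in calls:
            assert set(c.verdicts) == set(FILTER_ORDER)

    def test_low_depth_fails_regardless_of_evidence(self, flat_noise_model):
        c = make_call(depth=90, alt_count=40, ref_fwd=25, ref_rev=25)
        self._run([c], flat_noise_model)
        assert not c.verdicts["depth"]

    def test_heterozygote_band_fails_germline_self(self, flat_noise_model):
        c = make_call(depth=2000, alt_count=960, alt_fwd=480, alt_rev=480)
        self._run([c], flat_noise_model)
        assert not c.verdicts["germline_self"]  # VAF 0.48

    def test_cohort_germline_locus_fails(self, flat_noise_model):
        c = make_call()
        self._run([c], flat_noise_model, cohort_germline=GermlineMask({("chr1", 500)}))
        assert not c.verdicts["germline_cohort"]

    def test_segdup_interval_fails(self, flat_noise_model):
        c = make_call(pos=500)
        self._run([c], flat_noise_model, segdup_mask=[("chr1", 400, 600)])
        assert not c.verdicts["segdup"]
        c2 = make_call(pos=700)
        self._run([c2], flat_noise_model, segdup_mask=[("chr1", 400, 600)])
        assert c2.verdicts["segdup"]

    def test_cluster_fails_three_near_calls_not_two(self, flat_noise_model):
        trio = [make_call(pos=p) for p in (1000, 1050, 1090)]
        self._run(trio, flat_noise_model)
        assert all(not c.verdicts["cluster"] for c in trio)
        pair = [make_call(pos=p) for p in (5000, 5050)]
        self._run(pair, flat_noise_model)
        assert all(c.verdicts["cluster"] for c in pair)

    def test_noise_explained_neighbors_do_not_cluster(self, flat_noise_model):
        # two 3-read noise-level neighbors around one strong call: the strong
        # call keeps its cluster pass because the neighbors fail the noise test
        weak1 = make_call(pos=1000, alt_count=3, alt_fwd=2, alt_rev=1)
        weak2 = make_call(pos=1090, alt_count=3, alt_fwd=1, alt_rev=2)
        strong = make_call(pos=1050, alt_count=40, alt_fwd=20, alt_rev=20)
        self._run([weak1, strong, weak2], flat_noise_model)
        assert strong.verdicts["cluster"]
        assert not weak1.verdicts["binomial_noise"]

    def test_mapq_parity(self, flat_noise_model):
        bad = make_call(mean_mapq_alt=50.0, mean_mapq_ref=60.0)
        ok = make_call(pos=9000, mean_mapq_alt=56.0, mean_mapq_ref=60.0)
        self._run([bad, ok], flat_noise_model)
        assert not bad.verdicts["mapq_parity"]
        assert ok.verdicts["mapq_parity"]

    def test_population_frequency_exclusion(self, flat_noise_model):
        common = make_call(pop_af=1e-3)
        missing = make_call(pos=8000, pop_af=None)
        self._run([common, missing], flat_noise_model)
        assert not common.verdicts["pop_af"]
        assert missing.verdicts["pop_af"]  # missing treated as novel

    def test_upstream_nonpass_rejected_by_default(self, flat_noise_model):
        c = make_call(upstream_filter="t_lod_low")
        self._run([c], flat_noise_model)
        assert not c.verdicts["upstream"]
        c2 = make_call(upstream_filter="t_lod_low")
        self._run([c2], flat_noise_model, thresholds=FilterThresholds(reject_upstream_nonpass=False))
        assert c2.verdicts["upstream"]

    def test_indels_bypass_binomial_noise(self, flat_noise_model):
        indel = make_call(ref="A", alt="AT", consequence="frameshift_indel", context=None)
        self._run([indel], flat_noise_model)
        assert indel.verdicts["binomial_noise"] and indel.noise_p is None

    def test_binomial_gate_uses_context_rate(self, flat_noise_model):
        strong = make_call(alt_count=20)  # 20 reads vs 1e-4 noise at 2000x
        weak = make_call(pos=7000, alt_count=3, alt_fwd=2, alt_rev=1)
        self._run([strong, weak], flat_noise_model)
        assert strong.verdicts["binomial_noise"]
        assert not weak.verdicts["binomial_noise"]

    def test_conservation_of_calls(self, flat_noise_model):
        calls = [make_call(pos=1000 + 300 * i, alt_count=3 + i) for i in range(12)]
        self._run(calls, flat_noise_model)
        n_pass = len(passing(calls))
        n_fail = sum(1 for c in calls if c.failed_filters)
        assert n_pass + n_fail == len(calls)
        att = attrition_table(calls)
        assert int(att.loc[att["filter"] == "PASS", "n_failing"].iloc[0]) == n_pass

    def test_missing_site_counts_is_an_error(self, flat_noise_model, small_cohort):
        c = make_call(subject_id="nobody")
        with pytest.raises(ValueError, match="no site counts"):
            apply_filters([c], small_cohort.site_counts, flat_noise_model)


class TestGermlineCollection:
    def test_germline_calls_match_truth(self, small_cohort):
        truth_loci = small_cohort.truth.germline_loci()
        found = set()
        for s in small_cohort.subjects:
            for c in collect_germline_calls(small_cohort.site_counts[s.subject_id], s.subject_id):
                found.add((c.chrom, c.pos))
        # at ~2000x every planted het/hom sits far above VAF 0.35
        assert found == truth_loci

    def test_mask_union(self, small_cohort):
        masks = [
            germline_mask_from_calls(
                collect_germline_calls(small_cohort.site_counts[s.subject_id], s.subject_id)
            )
            for s in small_cohort.subjects
        ]
        union = GermlineMask.union(masks)
        assert len(union) >= max(len(m) for m in masks)


class TestCalibration:
    def _candidates(self, spectrum_calls, noise_p=1e-9):
        out = []
        for i, (ref, alt) in enumerate(spectrum_calls):
            ctx = {"C": "ACA", "T": "ATA", "G": "AGA", "A": "AAA"}[ref]
            c = make_call(pos=100 + 17 * i, ref=ref, alt=alt, context=ctx)
            c.verdicts = {name: True for name in FILTER_ORDER}
            c.noise_p = noise_p
            out.append(c)
        return out

    def _germline(self, n_per_class=20):
        pairs = [("C", "A"), ("C", "G"), ("C", "T"), ("T", "A"), ("T", "C"), ("T", "G")]
        calls = []
        for j, (ref, alt) in enumerate(pairs):
            for i in range(n_per_class):
                calls.append(
                    make_call(pos=10_000 + 100 * j + i, ref=ref, alt=alt, context=None)
                )
        return calls

    def test_identical_spectra_return_largest_alpha(self):
        germ = self._germline()
        somatic = self._candidates(
            [("C", "A"), ("C", "G"), ("C", "T"), ("T", "A"), ("T", "C"), ("T", "G")] * 15
        )
        alpha = calibrate_sensitivity(somatic, germ)
        assert alpha == max(DEFAULT_ALPHA_GRID)

    def test_returned_alpha_is_grid_member(self):
        germ = self._germline()
        somatic = self._candidates([("C", "T")] * 60)  # maximally C>T-skewed
        with pytest.warns(UserWarning):
            alpha = calibrate_sensitivity(somatic, germ)
        assert alpha in DEFAULT_ALPHA_GRID

    def test_ct_skew_forces_stringency(self):
        germ = self._germline()
        balanced = self._candidates(
            [("C", "A"), ("C", "G"), ("C", "T"), ("T", "A"), ("T", "C"), ("T", "G")] * 15
        )
        # C>T-heavy set whose excess calls are weak-evidence (large noise p)
        skew = balanced + self._candidates([("C", "T")] * 90, noise_p=5e-4)
        a_bal = calibrate_sensitivity(balanced, germ)
        a_skew = calibrate_sensitivity(skew, germ)
        assert a_skew < a_bal

    def test_requires_enough_germline(self):
        with pytest.raises(ValueError, match="50"):
            calibrate_sensitivity([], self._germline(n_per_class=5))

    def test_spectrum_strand_collapse_and_unique(self):
        calls = [
            make_call(pos=1, ref="G", alt="A"),  # counts as C>T
            make_call(pos=1, ref="G", alt="A"),  # duplicate locus
            make_call(pos=2, ref="C", alt="T"),
        ]
        assert substitution_spectrum(calls).tolist() == [0, 0, 3, 0, 0, 0]
        assert substitution_spectrum(calls, unique_loci=True).tolist() == [0, 0, 2, 0, 0, 0]


class TestConsequenceSummary:
    def test_hand_tally_20_calls(self):
        calls = []
        spec = [("stopgain", 3), ("frameshift_indel", 2), ("nonsynonymous_SNV", 14), ("splice", 1)]
        pos = 100
        for csq, n in spec:
            for _ in range(n):
                is_snv = csq in ("nonsynonymous_SNV", "stopgain")
                calls.append(
                    make_call(
                        pos=pos,
                        consequence=csq,
                        cadd=30.0 if csq == "nonsynonymous_SNV" else None,
                        polyphen="D" if csq == "nonsynonymous_SNV" else None,
                    )
                )
                pos += 50
        s = classify_consequence_summary(calls)["all"]
        assert s["n_total"] == 20
        assert s["stopgain_n"] == 3 and s["stopgain_pct"] == 15.0
        assert s["frameshift_indel_n"] == 2 and s["frameshift_indel_pct"] == 10.0
        assert s["snv_n"] == 14 and s["snv_pct"] == 70.0
        assert s["cadd20_denominator"] == 14 and s["cadd20_pct"] == 100.0

    def test_empty_set_gives_zero_table(self):
        assert classify_consequence_summary([]) == {}

    def test_unclassifiable_snv_excluded_from_cadd_denominator(self):
        calls = [
            make_call(pos=100, cadd=25.0, polyphen="D"),
            make_call(pos=200, cadd=None, polyphen=None),
        ]
        s = classify_consequence_summary(calls)["all"]
        assert s["cadd20_denominator"] == 1
        assert s["cadd20_pct"] == 100.0
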