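"""Group comparisons, age/depth associations and amplicon concordance."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from deepsoma.calls import nonsynonymous
from deepsoma.cohort import (
    age_burden_association,
    amplicon_concordance,
    burden_table,
    depth_count_association,
    group_compare,
    sex_compare,
    vaf_age_compare,
)
from deepsoma.panel import Subject


def burdens_frame(values_by_group, ages=None, depths=None, sexes=None):
    rows = []
    i = 0
    for group, values in values_by_group.items():
        for v in values:
            rows.append(
                {
                    "subject_id": f"S{i}",
                    "group": group,
                    "age": ages[i] if ages else 30 + i,
                    "sex": sexes[i] if sexes else ("F" if i % 2 else "M"),
                    "median_depth": depths[i] if depths else 2000.0 + 10 * i,
                    "n_total": v,
                    "n_nonsyn_expressed": v,
                    "n_syn_expressed": 0,
                    "mean_vaf": 0.005,
                    "vafs": [0.005],
                }
            )
            i += 1
    return pd.DataFrame(rows)


def mwu_exact_oracle(x, y):
    """Two-sided p by full enumeration of rank splits (small n, no ties)."""
    pooled = sorted(x + y)
    n1 = len(x)
    u_obs = sum(1 for a in x for b in y if a > b)
    us = []
    for comb in combinations(range(len(pooled)), n1):
        xs = [pooled[i] for i in comb]
        ys = [pooled[i] for i in range(len(pooled)) if i not in comb]
        us.append(sum(1 for a in xs for b in ys if a > b))
    us = np.array(us)
    mean_u = len(x) * len(y) / 2
    return float(np.mean(np.abs(us - mean_u) >= abs(u_obs - mean_u)))


class TestGroupCompare:
    def test_separated_groups_minimal_exact_p(self):
        b = burdens_frame({"case": [1, 2, 3], "control": [10, 11, 12]})
        p = group_compare(b, "n_total")
        assert p == pytest.approx(0.1, abs=1e-12)  # minimal two-sided p for 3 vs 3
        assert p == pytest.approx(mwu_exact_oracle([1, 2, 3], [10, 11, 12]), abs=1e-12)

    def test_all_tied_degenerate(self):
        b = burdens_frame({"case": [4, 4, 4], "control": [4, 4, 4]})
        assert group_compare(b, "n_total") == 1.0

    def test_label_swap_invariance(self):
        b1 = burdens_frame({"case": [3, 9, 4, 8], "control": [5, 1, 7, 2]})
        b2 = burdens_frame({"case": [5, 1, 7, 2], "control": [3, 9, 4, 8]})
        assert group_compare(b1, "n_total") == pytest.approx(
            group_compare(b2, "n_total"), rel=1e-12
        )

    def test_needs_two_per_group(self):
        with pytest.raises(ValueError):
            group_compare(burdens_frame({"case": [1], "control": [2, 3]}), "n_total")

    def test_sex_compare_runs(self):
        b = burdens_frame(
            {"case": [1, 5, 3, 8], "control": [2, 6, 4, 9]},
            sexes=list("FFMM") + list("FMFM"),
        )
        assert 0 < sex_compare(b, "n_nonsyn_expressed") <= 1


class TestAgeAssociations:
    def test_monotone_burden_gives_tau_one(self):
        ages = list(range(25, 45))
        b = burdens_frame({"case": list(range(20))}, ages=ages, depths=[2000.0] * 20)
        tau, p = age_burden_association(b)
        assert tau == pytest.approx(1.0)
        assert p < 0.001

    def test_depth_scaling_leaves_tau_unchanged(self):
        rng = np.random.default_rng(3)
        n = 15
        ages = rng.integers(23, 57, n).tolist()
        counts = rng.poisson(15, n)
        d1 = [2000.0] * n
        b1 = burdens_frame({"case": counts.tolist()}, ages=ages, depths=d1)
        b2 = burdens_frame({"case": counts.tolist()}, ages=ages, depths=[3 * d for d in d1])
        t1, _ = age_burden_association(b1)
        t2, _ = age_burden_association(b2)
        assert t1 == pytest.approx(t2, rel=1e-12)

    def test_null_p_values_uniform(self):
        """Burden independent of age: p over 400 seeds is ~Uniform(0,1)."""
        ps = []
        for seed in range(400):
            rng = np.random.default_rng(seed)
            n = 42
            b = burdens_frame(
                {"case": rng.poisson(15, n).tolist()},
                ages=rng.integers(23, 58, n).tolist(),
                depths=rng.uniform(1500, 3500, n).tolist(),
            )
            ps.append(age_burden_association(b)[1])
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_requires_ten_subjects(self):
        with pytest.raises(ValueError):
            age_burden_association(burdens_frame({"case": [1, 2, 3]}))


class TestDepthAssociation:
    def test_exact_pair_enumeration_n6(self):
        depths = [1500.0, 1800.0, 2100.0, 2500.0, 2900.0, 3300.0]
        counts = [4, 9, 7, 12, 11, 20]
        b = burdens_frame({"case": counts}, depths=depths)
        tau, _ = depth_count_association(b)
        # oracle: concordant/discordant pair counting (no ties here)
        conc = disc = 0
        for (d1, c1), (d2, c2) in combinations(zip(depths, counts), 2):
            s = np.sign((d1 - d2) * (c1 - c2))
            conc += s > 0
            disc += s < 0
        n_pairs = 15
        assert tau == pytest.approx((conc - disc) / n_pairs, rel=1e-12)

    def test_degenerate_counts(self):
        b = burdens_frame({"case": [5, 5, 5, 5]})
        assert depth_count_association(b) == (0.0, 1.0)


class TestVafAgeCompare:
    def _frame(self, young_vafs, old_vafs):
        rows = []
        for i, v in enumerate(young_vafs):
            rows.append({"subject_id": f"Y{i}", "group": "case", "age": 25, "sex": "F",
                         "median_depth": 2000.0, "n_total": len(v),
                         "n_nonsyn_expressed": len(v), "n_syn_expressed": 0,
                         "mean_vaf": np.mean(v), "vafs": v})
        for i, v in enumerate(old_vafs):
            rows.append({"subject_id": f"O{i}", "group": "control", "age": 50, "sex": "F",
                         "median_depth": 2000.0, "n_total": len(v),
                         "n_nonsyn_expressed": len(v), "n_syn_expressed": 0,
                         "mean_vaf": np.mean(v), "vafs": v})
        return pd.DataFrame(rows)

    def test_identical_lists_p_one(self):
        v = [0.002, 0.005, 0.009]
        b = self._frame([v], [v])
        my, mo, p = vaf_age_compare(b)
        assert my == pytest.approx(mo)
        assert p == 1.0

    def test_mean_matches_hand_sum(self):
        b = self._frame([[0.002, 0.004]], [[0.01, 0.02, 0.03]])
        my, mo, _ = vaf_age_compare(b)
        assert my == pytest.approx(0.003)
        assert mo == pytest.approx(0.02)

    def test_empty_band_is_error(self):
        b = self._frame([[0.002]], [])
        with pytest.raises(ValueError, match="empty"):
            vaf_age_compare(b)

    def test_power_against_doubled_clone_size(self):
        """A 2x VAF shift with age is detected in >= 80% of seeds at ~110+115 VAFs."""
        detected = 0
        n_seeds = 40
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            young = [list(np.exp(rng.normal(np.log(0.005), 0.8, 11))) for _ in range(10)]
            old = [list(np.exp(rng.normal(np.log(0.010), 0.8, 11))) for _ in range(10)]
            _, _, p = vaf_age_compare(self._frame(young, old))
            detected += p < 0.05
        assert detected / n_seeds >= 0.8


class TestAmpliconConcordance:
    def test_true_variant_confirmed(self):
        fold, verdict = amplicon_concordance(0.005, 0.004, 0.0001)
        assert fold == pytest.approx(0.8)
        assert verdict == "confirmed"

    def test_collapsing_variant_in_reference_dna_is_artifact(self):
        fold, verdict = amplicon_concordance(0.005, 0.0003, 0.0003)
        assert fold == pytest.approx(0.06)
        assert verdict == "artifact"

    def test_identity_with_clean_reference_confirmed(self):
        fold, verdict = amplicon_concordance(0.004, 0.004, 0.0)
        assert fold == pytest.approx(1.0)
        assert verdict == "confirmed"

    def test_between_regimes_indeterminate(self):
        _, verdict = amplicon_concordance(0.01, 0.004, 0.002)
        assert verdict == "indeterminate"

    def test_zero_panel_vaf_rejected(self):
        with pytest.raises(ValueError):
            amplicon_concordance(0.0, 0.001, 0.0)


class TestBurdenTable:
    def test_recount_matches_direct_tally(self, small_cohort):
        from deepsoma.filters import apply_filters
        from deepsoma.noise import tabulate_noise

        models = {
            sid: tabulate_noise(df) for sid, df in small_cohort.site_counts.items()
        }
        calls = small_cohort.all_candidates()
        apply_filters(calls, None, models)
        passing = [c for c in calls if c.passed]
        bt = burden_table(passing, small_cohort.subjects).set_index("subject_id")
        for s in small_cohort.subjects:
            mine = [c for c in passing if c.subject_id == s.subject_id]
            assert bt.loc[s.subject_id, "n_total"] == len(mine)
            expected_nonsyn = len(
                [c for c in nonsynonymous(mine) if c.expressed_in_cd8]
            )
            assert bt.loc[s.subject_id, "n_nonsyn_expressed"] == expected_nonsyn
            assert len(bt.loc[s.subject_id, "vafs"]) == len(mine)
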