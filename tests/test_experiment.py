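import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from shockbias.classify import classify_cohort
from shockbias.cohort import simulate_cohort
from shockbias.config import MasterConfig
from shockbias.errors import StructuralError
from shockbias.experiment import (CLASSES, compare_schemes,
                                  group_transfusion_stats,
                                  joint_class_fraction,
                                  postprocessing_spearman, run_all_scenarios,
                                  run_scenario)
from tests.conftest import make_tables


class TestJointClassFraction:
    def test_direct_count(self):
        classes = pd.DataFrame(
            {
                "hr_class": [1, 2, 3, 4],
                "sbp_class": [1, 1, 3, 2],
                "gcs_class": [1, 4, 3, 3],
                "bd_class": [2, 2, 2, 2],
                "composite_class": [1, 4, 3, 4],
            }
        )
        assert joint_class_fraction(classes, ("hr", "sbp", "gcs")) == 0.5
        assert joint_class_fraction(
            classes, ("hr", "sbp", "gcs", "bd")
        ) == 0.0

    def test_singleton_member_always_agrees(self):
        classes = pd.DataFrame({"hr_class": [1, 2, 3]})
        assert joint_class_fraction(classes, ("hr",)) == 1.0

    def test_empty_table_rejected(self):
        with pytest.raises(StructuralError):
            joint_class_fraction(pd.DataFrame({"hr_class": []}), ("hr",))

    def test_empty_members_rejected(self):
        with pytest.raises(StructuralError):
            joint_class_fraction(pd.DataFrame({"hr_class": [1]}), ())


class TestGroupStats:
    def test_hand_computed(self):
        cohort, classes = make_tables(
            transfusion=[0, 2, 4],
            singleton_classes=[2, 2, 2],
            composite_classes=[2, 2, 2],
        )
        out = group_transfusion_stats(cohort, classes, "bd")
        assert out[2].n == 3
        assert out[2].mean == pytest.approx(2.0)
        assert out[2].sd == pytest.approx(2.0)
        assert out[1].n == 0 and out[1].mean is None and out[1].sd is None

    def test_partition_conservation(self, equal_cohort):
        classes = classify_cohort(equal_cohort, ("hr", "sbp", "gcs"), seed=1)
        for scheme in ("composite", "bd", "hr", "sbp", "gcs"):
            out = group_transfusion_stats(equal_cohort, classes, scheme)
            assert sum(g.n for g in out.values()) == len(equal_cohort)

    def test_misaligned_tables_rejected(self):
        cohort, classes = make_tables([0, 1], [1, 1], [1, 1])
        with pytest.raises(StructuralError):
            group_transfusion_stats(cohort, classes.iloc[:1], "bd")

    def test_unknown_scheme_rejected(self):
        cohort, classes = make_tables([0.0], [1], [1])
        with pytest.raises(StructuralError):
            group_transfusion_stats(cohort, classes, "lactate")

    def test_scheme_means_increase_with_class(self, master):
        cohort = simulate_cohort(master.scenario("equal"))
        classes = classify_cohort(cohort, ("hr", "sbp", "gcs"), seed=1)
        for scheme in ("bd", "hr", "sbp"):
            out = group_transfusion_stats(cohort, classes, scheme)
            means = [out[c].mean for c in CLASSES if out[c].mean is not None]
            assert all(a <= b for a, b in zip(means, means[1:]))
        # gcs classes I and II are random halves of the GCS-15 patients, so
        # their means coincide only in expectation; monotonicity is exact
        # from II upward
        out = group_transfusion_stats(cohort, classes, "gcs")
        assert out[1].mean == pytest.approx(out[2].mean, abs=0.3)
        assert out[2].mean <= out[3].mean <= out[4].mean


class TestCompareSchemes:
    def test_identical_groups_null(self):
        cohort, classes = make_tables(
            transfusion=[0, 1, 2, 3],
            singleton_classes=[2, 2, 2, 2],
            composite_classes=[2, 2, 2, 2],
        )
        cmp2 = compare_schemes(cohort, classes, "bd")[1]
        assert cmp2.t_statistic == pytest.approx(0.0)
        assert cmp2.p_value == pytest.approx(1.0)

    def test_zero_variance_flagged_infinite(self):
        cohort, classes = make_tables(
            transfusion=[0, 0, 0, 0, 2, 2, 2, 2],
            singleton_classes=[2] * 4 + [1] * 4,
            composite_classes=[1] * 4 + [2] * 4,
        )
        cmp2 = compare_schemes(cohort, classes, "bd")[1]
        assert cmp2.degenerate
        assert cmp2.t_statistic == -math.inf
        assert cmp2.p_value == 0.0

    def test_textbook_pooled_formula_oracle(self):
        # groups a=(0,0,0,1), b=(2,2,2,3): hand-computable on 8 numbers
        cohort, classes = make_tables(
            transfusion=[0, 0, 0, 1, 2, 2, 2, 3],
            singleton_classes=[2] * 4 + [1] * 4,
            composite_classes=[1] * 4 + [2] * 4,
        )
        cmp2 = compare_schemes(cohort, classes, "bd")[1]
        # textbook pooled-variance computation, written out independently
        a = np.array([0.0, 0.0, 0.0, 1.0])
        b = np.array([2.0, 2.0, 2.0, 3.0])
        sp2 = ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)) / (
            a.size + b.size - 2
        )
        t_ref = (a.mean() - b.mean()) / math.sqrt(sp2 * (1 / a.size + 1 / b.size))
        p_ref = 2 * stats.t.sf(abs(t_ref), a.size + b.size - 2)
        assert t_ref == pytest.approx(-4 * math.sqrt(2))
        assert cmp2.t_statistic == pytest.approx(t_ref, abs=1e-12)
        assert cmp2.p_value == pytest.approx(p_ref, abs=1e-12)
        assert not cmp2.degenerate

    def test_small_groups_flagged_not_fabricated(self):
        cohort, classes = make_tables(
            transfusion=[0, 1, 2],
            singleton_classes=[2, 1, 1],
            composite_classes=[1, 2, 2],
        )
        cmp2 = compare_schemes(cohort, classes, "bd")[1]
        assert cmp2.degenerate
        assert cmp2.t_statistic is None and cmp2.p_value is None

    def test_welch_differs_under_unequal_variance(self):
        rng = np.random.default_rng(0)
        tr = np.concatenate([rng.normal(0, 0.5, 30), rng.normal(1, 4, 70)])
        cohort, classes = make_tables(
            transfusion=tr,
            singleton_classes=[2] * 30 + [1] * 70,
            composite_classes=[1] * 30 + [2] * 70,
        )
        pooled = compare_schemes(cohort, classes, "bd")[1]
        welch = compare_schemes(cohort, classes, "bd", welch=True)[1]
        assert pooled.t_statistic != pytest.approx(welch.t_statistic)


class TestPostprocessingSpearman:
    def test_perfect_monotone(self):
        cohort, _ = make_tables([0, 1, 2, 3], [1] * 4, [1] * 4)
        cohort["hr"] = cohort["transfusion"] * 2 + 10
        out = postprocessing_spearman(cohort)
        assert out["hr"] == pytest.approx(1.0)

    def test_constant_column_flagged(self):
        cohort, _ = make_tables([0, 1, 2, 3], [1] * 4, [1] * 4)
        out = postprocessing_spearman(cohort)  # hr column is constant
        assert out["hr"] is None

    def test_too_few_rows(self):
        cohort, _ = make_tables([0, 1], [1, 1], [1, 1])
        with pytest.raises(StructuralError):
            postprocessing_spearman(cohort)


def naive_summary(cohort, classes, singleton):
    """Plain-loop reference implementation of every summary statistic."""
    per_class = {}
    for cls in (1, 2, 3, 4):
        a, b = [], []
        for i in range(len(cohort)):
            if classes[f"{singleton}_class"].iloc[i] == cls:
                a.append(cohort["transfusion"].iloc[i])
            if classes["composite_class"].iloc[i] == cls:
                b.append(cohort["transfusion"].iloc[i])
        t = p = None
        if len(a) >= 2 and len(b) >= 2 and (np.std(a) > 0 or np.std(b) > 0):
            na, nb = len(a), len(b)
            va = sum((x - np.mean(a)) ** 2 for x in a) / (na - 1)
            vb = sum((x - np.mean(b)) ** 2 for x in b) / (nb - 1)
            sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
            t = (np.mean(a) - np.mean(b)) / math.sqrt(sp2 * (1 / na + 1 / nb))
            p = 2 * stats.t.sf(abs(t), na + nb - 2)
        per_class[cls] = (len(a), len(b),
                          np.mean(a) if a else None, np.mean(b) if b else None,
                          t, p)
    same = 0
    for i in range(len(classes)):
        row = classes.iloc[i]
        if row["hr_class"] == row["sbp_class"] == row["gcs_class"]:
            same += 1
    return per_class, same / len(classes)


class TestOracleEquivalence:
    def test_naive_loop_reference(self, small_master):
        cfg = small_master.scenario("equal")
        cohort = simulate_cohort(cfg)
        classes = classify_cohort(cohort, cfg.composite_members, cfg.seed)
        summary = run_scenario(cfg)
        ref_classes, ref_joint = naive_summary(cohort, classes, "bd")
        assert summary.joint_class_fraction == pytest.approx(ref_joint,
                                                             abs=1e-10)
        for cmp in summary.comparisons:
            na, nb, ma, mb, t, p = ref_classes[cmp.shock_class]
            assert cmp.n_singleton == na
            assert cmp.n_composite == nb
            if ma is not None:
                assert cmp.mean_singleton == pytest.approx(ma, abs=1e-10)
            if t is not None and cmp.t_statistic is not None:
                assert cmp.t_statistic == pytest.approx(t, abs=1e-10)
                assert cmp.p_value == pytest.approx(p, abs=1e-10)


class TestRunScenario:
    def test_seed_determinism(self, small_master):
        a = run_scenario(small_master.scenario("equal"))
        b = run_scenario(small_master.scenario("equal"))
        assert a.to_dict() == b.to_dict()

    def test_smoke_n50(self):
        summary = run_scenario(MasterConfig(seed=5, n=50).scenario("equal"))
        assert 0.0 <= summary.joint_class_fraction <= 1.0
        assert len(summary.comparisons) == 4
        # degenerate classes allowed at tiny n, but they must be flagged
        for cmp in summary.comparisons:
            if cmp.n_singleton < 2 or cmp.n_composite < 2:
                assert cmp.degenerate

    def test_warnings_record_placeholders(self, small_master):
        summary = run_scenario(small_master.scenario("equal"))
        assert any("placeholder" in w for w in summary.warnings)

    def test_joint_fraction_reported_range(self, master):
        summary = run_scenario(master.scenario("equal"))
        assert 0.10 <= summary.joint_class_fraction <= 0.18

    def test_swap_scenario_favors_hr(self, master):
        summary = run_scenario(master.scenario("swap-equal"))
        assert summary.comparison_singleton == "hr"
        assert summary.composite_members == ("bd", "sbp", "gcs")
        for cmp in summary.comparisons[1:]:
            assert cmp.mean_singleton > cmp.mean_composite


class TestRunAllScenarios:
    def test_four_summaries(self, small_master):
        out = run_all_scenarios(small_master)
        assert set(out) == {"equal", "unequal", "swap-equal", "swap-unequal"}
        assert all(s is not None for s in out.values())

    def test_equal_and_swap_share_cohort_draw(self, small_master):
        eq = small_master.scenario("equal")
        sw = small_master.scenario("swap-equal")
        assert eq.seed == sw.seed
        pd.testing.assert_frame_equal(simulate_cohort(eq), simulate_cohort(sw))

    def test_symmetry_of_allocation_bias(self, master):
        # same-direction, comparable-size bias whichever predictor is the
        # singleton: the bias belongs to the allocation rule
        out = run_all_scenarios(master)
        for cls_idx in (1, 2, 3):
            bd_gap = (out["equal"].comparisons[cls_idx].mean_singleton
                      - out["equal"].comparisons[cls_idx].mean_composite)
            hr_gap = (out["swap-equal"].comparisons[cls_idx].mean_singleton
                      - out["swap-equal"].comparisons[cls_idx].mean_composite)
            assert bd_gap > 0 and hr_gap > 0
            assert 1 / 3 < bd_gap / hr_gap < 3
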