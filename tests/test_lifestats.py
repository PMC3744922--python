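import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from wormfret import (
    GeneratorConfig,
    LifeStatsError,
    dunnett_test,
    kaplan_meier_curve,
    logrank_test,
    one_way_anova,
    percent_alive_curve,
    simulate_survival,
    simulate_traits,
    survival_to_frame,
    traits_to_frame,
)


def trait_frame(groups: dict[str, list[float]], trait: str = "pumps_per_min"):
    rows = []
    for strain, values in groups.items():
        for i, v in enumerate(values):
            rows.append(
                {"worm_id": f"{strain}-{i}", "strain": strain, "trait": trait, "value": v}
            )
    return pd.DataFrame(rows)


def survival_frame(groups: dict[str, list[int]], censored=None):
    rows = []
    for strain, days in groups.items():
        for i, d in enumerate(days):
            c = censored[strain][i] if censored else False
            rows.append(
                {"worm_id": f"{strain}-{i}", "strain": strain, "lifespan_days": d, "censored": c}
            )
    return pd.DataFrame(rows)


class TestOneWayAnova:
    def test_identical_groups_give_f_zero(self):
        res = one_way_anova(trait_frame({"a": [1, 2, 3], "b": [1, 2, 3]}), "pumps_per_min")
        assert res.F == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_hand_decomposed_three_groups(self):
        """{1,2},{3,4},{5,6}: SS_between=16 (df 2), SS_within=1.5 (df 3), F=16."""
        res = one_way_anova(
            trait_frame({"a": [1, 2], "b": [3, 4], "c": [5, 6]}), "pumps_per_min"
        )
        assert res.ss_between == pytest.approx(16.0)
        assert res.ss_within == pytest.approx(1.5)
        assert (res.df_between, res.df_within) == (2, 3)
        assert res.F == pytest.approx(16.0)

    def test_matches_scipy_oracle(self):
        rng = np.random.default_rng(5)
        groups = {f"g{i}": list(rng.normal(10 + i, 2, 12)) for i in range(4)}
        res = one_way_anova(trait_frame(groups), "pumps_per_min")
        f_ref, p_ref = stats.f_oneway(*groups.values())
        assert res.F == pytest.approx(f_ref, rel=1e-10)
        assert res.p_value == pytest.approx(p_ref, rel=1e-10)

    @given(
        data=st.lists(
            st.lists(st.floats(-100, 100), min_size=2, max_size=8),
            min_size=2,
            max_size=6,
        )
    )
    @settings(max_examples=60, deadline=None)
    def test_sum_of_squares_identity(self, data):
        groups = {f"g{i}": vals for i, vals in enumerate(data)}
        res = one_way_anova(trait_frame(groups), "pumps_per_min")
        assert res.ss_total == pytest.approx(
            res.ss_between + res.ss_within, rel=1e-9, abs=1e-9
        )

    def test_type_one_error_calibrated(self):
        """Equal-mean groups: rejection rate at alpha=0.05 stays nominal."""
        rng = np.random.default_rng(99)
        rejections = 0
        reps = 1000
        for _ in range(reps):
            groups = {f"g{i}": list(rng.normal(0, 1, 10)) for i in range(8)}
            res = one_way_anova(trait_frame(groups), "pumps_per_min")
            rejections += res.p_value < 0.05
        assert 0.03 <= rejections / reps <= 0.07

    def test_small_group_rejected_with_name(self):
        with pytest.raises(LifeStatsError, match="b"):
            one_way_anova(trait_frame({"a": [1, 2], "b": [3]}), "pumps_per_min")

    def test_single_group_rejected(self):
        with pytest.raises(LifeStatsError):
            one_way_anova(trait_frame({"a": [1, 2, 3]}), "pumps_per_min")


class TestDunnett:
    def test_single_treatment_reduces_to_t_test(self):
        rng = np.random.default_rng(3)
        groups = {"N2": list(rng.normal(0, 1, 15)), "t": list(rng.normal(0.8, 1, 15))}
        res = dunnett_test(trait_frame(groups), "pumps_per_min", control="N2", seed=1)
        t_ref = stats.ttest_ind(groups["t"], groups["N2"], equal_var=True)
        cmp_ = res.comparisons[0]
        assert cmp_.t_statistic == pytest.approx(t_ref.statistic, rel=1e-10)
        assert cmp_.p_adjusted == pytest.approx(t_ref.pvalue, abs=0.01)

    def test_matches_scipy_dunnett_oracle(self):
        rng = np.random.default_rng(8)
        control = rng.normal(10, 2, 12)
        t1 = rng.normal(11.5, 2, 12)
        t2 = rng.normal(10, 2, 12)
        t3 = rng.normal(8, 2, 12)
        frame = trait_frame(
            {"N2": list(control), "a": list(t1), "b": list(t2), "c": list(t3)}
        )
        res = dunnett_test(frame, "pumps_per_min", control="N2", seed=2)
        ref = stats.dunnett(t1, t2, t3, control=control)
        ours = {c.strain: c.p_adjusted for c in res.comparisons}
        for name, p_ref in zip(("a", "b", "c"), ref.pvalue):
            assert ours[name] == pytest.approx(p_ref, abs=0.015)

    def test_adjusted_p_at_least_unadjusted(self):
        rng = np.random.default_rng(12)
        groups = {"N2": list(rng.normal(0, 1, 10))}
        groups.update({f"t{i}": list(rng.normal(0.5, 1, 10)) for i in range(4)})
        frame = trait_frame(groups)
        res = dunnett_test(frame, "pumps_per_min", control="N2", seed=4)
        df = res.df
        for cmp_ in res.comparisons:
            p_unadj = 2 * stats.t.sf(abs(cmp_.t_statistic), df)
            assert cmp_.p_adjusted >= p_unadj - 0.01

    def test_adjusted_p_monotone_in_t(self):
        rng = np.random.default_rng(13)
        groups = {"N2": list(rng.normal(0, 1, 10))}
        groups.update({f"t{i}": list(rng.normal(i * 0.7, 1, 10)) for i in range(4)})
        res = dunnett_test(trait_frame(groups), "pumps_per_min", control="N2", seed=5)
        cmps = sorted(res.comparisons, key=lambda c: abs(c.t_statistic))
        ps = [c.p_adjusted for c in cmps]
        assert ps == sorted(ps, reverse=True)

    def test_familywise_error_controlled(self):
        """6 equal-mean groups: FWER at nominal 0.05 stays <= 0.07."""
        rng = np.random.default_rng(77)
        reps, false_rejections = 1000, 0
        for r in range(reps):
            groups = {"N2": list(rng.normal(0, 1, 10))}
            groups.update({f"t{i}": list(rng.normal(0, 1, 10)) for i in range(5)})
            res = dunnett_test(
                trait_frame(groups), "pumps_per_min", control="N2",
                n_mc=4000, seed=r,
            )
            false_rejections += any(c.p_adjusted < 0.05 for c in res.comparisons)
        assert false_rejections / reps <= 0.07

    def test_power_for_large_shift(self):
        """A 3-pooled-SD shift at n=10/group is detected decisively."""
        rng = np.random.default_rng(21)
        groups = {
            "N2": list(rng.normal(0, 1, 10)),
            "shifted": list(rng.normal(3.0, 1, 10)),
            "null": list(rng.normal(0, 1, 10)),
        }
        res = dunnett_test(trait_frame(groups), "pumps_per_min", control="N2", seed=6)
        p = {c.strain: c.p_adjusted for c in res.comparisons}
        assert p["shifted"] < 0.001

    def test_missing_control_rejected(self):
        with pytest.raises(LifeStatsError, match="control"):
            dunnett_test(
                trait_frame({"a": [1, 2], "b": [3, 4]}), "pumps_per_min", control="N2"
            )


class TestPercentAliveCurve:
    def test_direct_count_example(self):
        curve = percent_alive_curve(survival_frame({"s": [2, 2, 4]}), "s")
        by_day = dict(zip(curve.days.tolist(), curve.pct_alive.tolist()))
        assert by_day[0] == pytest.approx(100.0)
        assert by_day[2] == pytest.approx(100 / 3)
        assert by_day[4] == pytest.approx(0.0)

    def test_starts_at_100_and_non_increasing_without_censoring(self):
        rng = np.random.default_rng(2)
        days = list(rng.integers(1, 30, 100))
        curve = percent_alive_curve(survival_frame({"s": days}), "s")
        assert curve.pct_alive[0] == 100.0
        assert (np.diff(curve.pct_alive) <= 1e-12).all()

    def test_all_censored_curve_undefined_after_followup(self):
        frame = survival_frame({"s": [1, 1, 1]}, censored={"s": [True, True, True]})
        curve = percent_alive_curve(frame, "s")
        assert curve.pct_alive[0] == 100.0
        assert curve.pct_alive[1] == 100.0  # still under observation on day 1

    def test_median_from_curve_matches_sample_median(self):
        """Odd n, no censoring: day the curve crosses 50% is the sample median."""
        rng = np.random.default_rng(9)
        days = list(rng.integers(1, 40, 101))
        curve = percent_alive_curve(survival_frame({"s": days}), "s")
        crossing = curve.days[np.argmax(curve.pct_alive < 50.0)]
        assert crossing == np.median(days)

    def test_matches_kaplan_meier_without_censoring(self):
        rng = np.random.default_rng(4)
        days = list(rng.integers(1, 25, 80))
        frame = survival_frame({"s": days})
        curve = percent_alive_curve(frame, "s")
        km = kaplan_meier_curve(frame, "s")
        km_by_day = dict(zip(km["day"], km["survival"]))
        for day, pct in zip(curve.days, curve.pct_alive):
            if float(day) in km_by_day:
                assert pct == pytest.approx(100 * km_by_day[float(day)], abs=1e-9)

    def test_empty_input_rejected(self):
        with pytest.raises(LifeStatsError):
            percent_alive_curve(survival_frame({"s": [1]}), "missing")


class TestLogrank:
    def test_identical_groups_null(self):
        frame = survival_frame({"a": [3, 5, 8], "b": [3, 5, 8]})
        res = logrank_test(frame[frame.strain == "a"], frame[frame.strain == "b"])
        assert res.chi_square == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_hand_tabulated_separated_groups(self):
        """a={1,2,3}, b={4,5,6}: O1=3, E1=1.15, V=0.6775 by hand tabulation."""
        frame = survival_frame({"a": [1, 2, 3], "b": [4, 5, 6]})
        res = logrank_test(frame[frame.strain == "a"], frame[frame.strain == "b"])
        assert res.observed[0] == pytest.approx(3.0)
        assert res.expected[0] == pytest.approx(1.15)
        assert res.chi_square == pytest.approx((3 - 1.15) ** 2 / 0.6775, rel=1e-9)
        assert res.p_value == pytest.approx(stats.chi2.sf(5.0517, 1), abs=1e-4)

    def test_observed_equals_expected_in_total(self):
        rng = np.random.default_rng(14)
        frame = survival_frame(
            {"a": list(rng.integers(1, 20, 40)), "b": list(rng.integers(1, 25, 35))}
        )
        res = logrank_test(frame[frame.strain == "a"], frame[frame.strain == "b"])
        assert sum(res.observed) == pytest.approx(sum(res.expected))

    def test_symmetric_in_group_labels(self):
        rng = np.random.default_rng(15)
        frame = survival_frame(
            {"a": list(rng.integers(1, 20, 30)), "b": list(rng.integers(1, 15, 30))}
        )
        ab = logrank_test(frame[frame.strain == "a"], frame[frame.strain == "b"])
        ba = logrank_test(frame[frame.strain == "b"], frame[frame.strain == "a"])
        assert ab.chi_square == pytest.approx(ba.chi_square, rel=1e-12)

    def test_invariant_to_constant_shift(self):
        rng = np.random.default_rng(16)
        days_a = rng.integers(1, 20, 30)
        days_b = rng.integers(1, 15, 30)
        f1 = survival_frame({"a": list(days_a), "b": list(days_b)})
        f2 = survival_frame({"a": list(days_a + 10), "b": list(days_b + 10)})
        r1 = logrank_test(f1[f1.strain == "a"], f1[f1.strain == "b"])
        r2 = logrank_test(f2[f2.strain == "a"], f2[f2.strain == "b"])
        assert r1.chi_square == pytest.approx(r2.chi_square, rel=1e-12)

    def test_matches_lifelines_oracle_with_ties(self):
        from lifelines.statistics import logrank_test as ll_logrank

        rng = np.random.default_rng(17)
        days_a = rng.integers(1, 12, 60)
        days_b = rng.integers(1, 10, 60)
        frame = survival_frame({"a": list(days_a), "b": list(days_b)})
        res = logrank_test(frame[frame.strain == "a"], frame[frame.strain == "b"])
        ref = ll_logrank(days_a, days_b)
        assert res.chi_square == pytest.approx(ref.test_statistic, rel=1e-6)
        assert res.p_value == pytest.approx(ref.p_value, rel=1e-6)

    def test_type_one_error_calibrated(self):
        """Same discrete lifespan distribution in both arms: nominal size."""
        rng = np.random.default_rng(31)
        reps, rejections = 1000, 0
        for _ in range(reps):
            a = np.maximum(1, np.rint(rng.normal(17, 3, 50)).astype(int))
            b = np.maximum(1, np.rint(rng.normal(17, 3, 50)).astype(int))
            frame = survival_frame({"a": list(a), "b": list(b)})
            res = logrank_test(frame[frame.strain == "a"], frame[frame.strain == "b"])
            rejections += res.p_value < 0.05
        assert 0.03 <= rejections / reps <= 0.07

    def test_no_events_rejected(self):
        frame = survival_frame({"a": [1, 2], "b": [3]}, censored={"a": [True, True], "b": [True]})
        with pytest.raises(LifeStatsError, match="no death events"):
            logrank_test(frame[frame.strain == "a"], frame[frame.strain == "b"])


def test_default_synthetic_panel_reproduces_significance_pattern():
    """Strain affects pumping and locomotion but not development or brood."""
    cfg = GeneratorConfig()
    frames = [
        traits_to_frame(simulate_traits(cfg, strain, 30, seed=500 + i))
        for i, strain in enumerate(cfg.strains)
    ]
    records = pd.concat(frames, ignore_index=True)
    p = {
        trait: one_way_anova(records, trait).p_value
        for trait in ("dev_time_h", "brood_size", "pumps_per_min", "bends_per_30s")
    }
    assert p["pumps_per_min"] < 1e-4
    assert p["bends_per_30s"] < 1e-4
    assert p["dev_time_h"] > 0.01
    assert p["brood_size"] > 0.01


def test_synuclein_lifespan_effect_significant_marker_effect_detection():
    """Log-rank flags the ~5-day synuclein deficit against wild type."""
    cfg = GeneratorConfig()
    n2 = survival_to_frame(simulate_survival(cfg, "N2", 60, seed=601))
    sc = survival_to_frame(simulate_survival(cfg, "SC+SV", 60, seed=602))
    res = logrank_test(n2, sc)
    assert res.p_value < 1e-4
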