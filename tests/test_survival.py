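"""Survival statistics checked against hand computations and brute force."""

import math

import numpy as np
import pandas as pd
import pytest

from ctmonitor.survival import (
    cox_univariate,
    dcb_rate,
    durable_clinical_benefit,
    kaplan_meier,
    logrank_test,
    mann_whitney_u,
    stratified_endpoint_report,
)

from _oracles import mantel_cox_statistic, mwu_enumeration_p


class TestKaplanMeier:
    def test_hand_product_limit(self):
        """Five events at 1..5: survival steps 0.8, 0.6, 0.4, ...; median 3."""
        curve = kaplan_meier([(t, 1) for t in (1, 2, 3, 4, 5)])
        surv_at = dict(zip(curve.times, curve.survival))
        assert surv_at[3.0] == pytest.approx(0.4)
        assert curve.median_weeks == 3.0

    def test_single_event_drops_to_zero(self):
        curve = kaplan_meier([(10.0, 1)])
        assert curve.survival[-1] == pytest.approx(0.0)
        assert curve.median_weeks == 10.0

    def test_all_censored_flat_median_undefined(self):
        curve = kaplan_meier([(5.0, 0), (8.0, 0), (12.0, 0)])
        assert np.all(curve.survival == 1.0)
        assert curve.median_weeks is None

    def test_uncensored_km_equals_empirical_survivor_function(self, rng):
        times = rng.exponential(20.0, size=40).round(1)
        curve = kaplan_meier([(t, 1) for t in times])
        for t, s in zip(curve.times, curve.survival):
            assert s == pytest.approx(np.mean(times > t))

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            kaplan_meier([])


class TestLogrank:
    def test_identical_groups_statistic_zero(self):
        g = [(3.0, 1), (7.0, 1), (9.0, 0)]
        res = logrank_test([g, list(g)])
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_hand_mantel_cox_two_by_two(self):
        """Group A events at 1,2; group B at 10,11: O-E and V sums give 49/17."""
        res = logrank_test([[(1, 1), (2, 1)], [(10, 1), (11, 1)]])
        assert res.statistic == pytest.approx(49 / 17, rel=1e-9)

    def test_matches_brute_force_on_random_data(self, rng):
        for _ in range(5):
            times = rng.exponential(10, size=12).round(2)
            events = rng.integers(0, 2, size=12)
            events[0] = 1
            labels = np.array([0] * 6 + [1] * 6)
            ours = logrank_test(
                [
                    list(zip(times[labels == 0], events[labels == 0])),
                    list(zip(times[labels == 1], events[labels == 1])),
                ]
            )
            oracle = mantel_cox_statistic(times, events, labels)
            assert ours.statistic == pytest.approx(oracle, rel=1e-8, abs=1e-10)

    def test_invariant_under_time_rescaling(self):
        g1 = [(1.0, 1), (4.0, 1), (6.0, 0)]
        g2 = [(2.0, 1), (3.0, 1), (8.0, 1)]
        a = logrank_test([g1, g2])
        b = logrank_test(
            [[(t * 7.0, e) for t, e in g1], [(t * 7.0, e) for t, e in g2]]
        )
        assert a.statistic == pytest.approx(b.statistic)

    def test_needs_two_nonempty_groups(self):
        with pytest.raises(ValueError):
            logrank_test([[(1.0, 1)]])
        with pytest.raises(ValueError):
            logrank_test([[(1.0, 1)], []])


class TestCox:
    def test_label_symmetric_data_gives_unit_hazard_ratio(self):
        base = [(2.0, 1), (5.0, 1), (9.0, 1), (12.0, 0)]
        records = base + base
        x = [0] * 4 + [1] * 4
        res = cox_univariate(records, x)
        assert res.converged
        assert res.hazard_ratio == pytest.approx(1.0, abs=1e-6)

    def test_two_point_tied_partial_likelihood(self):
        """Breslow likelihood e^b/(1+e^b)^2 for two tied events peaks at b=0."""
        res = cox_univariate([(5.0, 1), (5.0, 1)], [0, 1])
        assert res.converged
        assert res.hazard_ratio == pytest.approx(1.0, abs=1e-6)

    def test_separated_event_times_flagged_not_raised(self):
        # every group-0 event precedes every group-1 time: monotone likelihood
        records = [(1.0, 1), (2.0, 1), (10.0, 1), (11.0, 1)]
        res = cox_univariate(records, [0, 0, 1, 1])
        assert not res.converged

    def test_recovers_planted_hazard_ratio(self, rng):
        n = 500
        x = np.array([0] * (n // 2) + [1] * (n // 2))
        # group 1 hazard halved -> scale doubled
        times = rng.exponential(np.where(x == 1, 20.0, 10.0))
        res = cox_univariate(list(zip(times, [1] * n)), x)
        assert res.converged
        assert 0.4 <= res.hazard_ratio <= 0.62
        assert res.ci_lower < res.hazard_ratio < res.ci_upper

    def test_time_rescaling_and_label_swap(self, rng):
        n = 60
        x = np.array([0] * 30 + [1] * 30)
        times = rng.exponential(np.where(x == 1, 30.0, 10.0))
        rec = list(zip(times, [1] * n))
        a = cox_univariate(rec, x)
        b = cox_univariate([(t * 3.5, e) for t, e in rec], x)
        c = cox_univariate(rec, 1 - x)
        assert a.log_hr == pytest.approx(b.log_hr, rel=1e-5)
        assert a.log_hr == pytest.approx(-c.log_hr, rel=1e-5)

    def test_requires_events_in_both_levels(self):
        with pytest.raises(ValueError):
            cox_univariate([(1.0, 1), (2.0, 0)], [0, 1])


class TestDCB:
    @pytest.mark.parametrize(
        "weeks, event, expected",
        [
            (30.0, 1, "true"),  # progressed, but after the 26-week mark
            (26.0, 0, "true"),
            (10.0, 1, "false"),
            (12.0, 0, "indeterminate"),  # censored before 26 weeks
        ],
    )
    def test_rule(self, weeks, event, expected):
        assert durable_clinical_benefit(weeks, event) == expected

    def test_partition_and_no_early_progression_in_true(self, rng):
        weeks = rng.exponential(30, size=200)
        events = rng.integers(0, 2, size=200)
        for w, e in zip(weeks, events):
            call = durable_clinical_benefit(w, int(e))
            assert call in ("true", "false", "indeterminate")
            if call == "true":
                assert not (e == 1 and w < 26.0)

    def test_rate_excludes_indeterminate(self):
        rate, n = dcb_rate([30.0, 10.0, 12.0], [1, 1, 0])
        assert n == 2 and rate == pytest.approx(0.5)
        rate, n = dcb_rate([5.0], [0])
        assert rate is None and n == 0


class TestMannWhitney:
    def test_disjoint_small_samples_exact(self):
        u, p = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(0.1)

    def test_identical_multisets_boundary(self):
        a = [1.0, 2.0, 3.0, 4.0]
        u, p = mann_whitney_u(a, list(a))
        assert u == pytest.approx(len(a) ** 2 / 2)
        assert p >= 0.9

    def test_exact_p_matches_enumeration(self, rng):
        for _ in range(3):
            a = rng.normal(0, 1, size=6)
            b = rng.normal(0.8, 1, size=6)
            _, p = mann_whitney_u(a, b)
            assert p == pytest.approx(mwu_enumeration_p(a, b), abs=1e-12)

    def test_large_sample_approximation_close_to_exact(self, rng):
        a = rng.normal(0, 1, size=8)
        b = rng.normal(1.0, 1, size=8)
        _, p_exact = mann_whitney_u(a, b)  # n<=16 and no ties -> exact
        res = __import__("scipy.stats", fromlist=["mannwhitneyu"]).mannwhitneyu(
            a, b, alternative="two-sided", method="asymptotic"
        )
        assert abs(p_exact - res.pvalue) < 0.01


class TestStratifiedReport:
    @staticmethod
    def _tables():
        clinical = pd.DataFrame(
            {
                "patient_id": list("abcdef"),
                "pfs_weeks": [40.0, 35.0, 5.0, 6.0, 20.0, 18.0],
                "pfs_event": [1, 1, 1, 1, 1, 1],
                "os_weeks": [80.0, 70.0, 15.0, 12.0, 40.0, 30.0],
                "os_event": [1, 1, 1, 1, 1, 1],
                "tps_stratum": ["<1%", ">=50%", "1-49%", "<1%", ">=50%", "unavailable"],
            }
        )
        dynamics = pd.DataFrame(
            {
                "patient_id": list("abcdef"),
                "category": ["decreasing", "decreasing", "increasing", "stable", "negative", "negative"],
                "relative_change": [-0.6, -0.5, 0.8, 0.1, None, None],
                "threshold": [0.3] * 6,
                "group_exclude_negative": ["decrease", "decrease", "no_decrease", "no_decrease", None, None],
                "group_include_negative": ["decrease", "decrease", "no_decrease", "no_decrease", "no_decrease", "no_decrease"],
            }
        )
        return clinical, dynamics

    def test_structure_and_group_medians(self):
        clinical, dynamics = self._tables()
        report = stratified_endpoint_report(clinical, dynamics)
        binary = report["binary_exclude_negative"]["groups"]
        assert binary["decrease"]["n"] == 2
        assert binary["decrease"]["median_pfs_weeks"] > binary["no_decrease"]["median_pfs_weeks"]
        assert set(report["four_level"]["groups"]) == {
            "decreasing",
            "increasing",
            "stable",
            "negative",
        }
        assert set(report["tps_strata"]) == {"tps_ge_1", "tps_lt_1"}

    def test_single_group_emits_no_pairwise_tests(self):
        clinical, dynamics = self._tables()
        only_dec = dynamics[dynamics["category"] == "decreasing"]
        report = stratified_endpoint_report(clinical, only_dec)
        assert "logrank_p" not in report["four_level"]["pfs"]

    def test_all_tps_unavailable_skips_tps_section(self):
        clinical, dynamics = self._tables()
        clinical["tps_stratum"] = "unavailable"
        report = stratified_endpoint_report(clinical, dynamics)
        assert report["tps_strata"] == {}
        assert report["four_level"]["groups"]  # dynamics section intact
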