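"""Rates, rate ratios, rate/risk differences, MDRR, stratification."""
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from vaxsafety.errors import EstimationError
from vaxsafety.estimation import (
    RateSummary,
    absolute_risk_difference,
    estimate_cell,
    incidence_rate,
    mdrr,
    person_time,
    poisson_irr,
    rate_difference,
    stratified_estimates,
)


class TestPersonTime:
    def test_full_window(self, cohort_of):
        cohort = cohort_of([(1, 0, 28)])
        assert person_time(cohort).iloc[0] == pytest.approx(28 / 365.25)

    def test_censored_at_event(self, cohort_of):
        cohort = cohort_of([(1, 0, 28)])
        ev = pd.Series([10.0], index=pd.Index([1], name="person_id"))
        assert person_time(cohort, ev).iloc[0] == pytest.approx(10 / 365.25)

    def test_empty_cohort(self, cohort_of):
        assert person_time(cohort_of([])).sum() == 0.0

    def test_negative_interval_rejected(self, cohort_of):
        cohort = cohort_of([(1, 50, 40)])
        with pytest.raises(EstimationError):
            person_time(cohort)


class TestIncidenceRate:
    @pytest.mark.parametrize(
        "events,py,expected",
        [(827, 136_523, 6.06), (442, 90_381, 4.89), (49, 5_037, 9.73)],
    )
    def test_published_cells_reproduce_printed_rates(self, events, py, expected):
        assert round(incidence_rate(events, py).rate_per_1000py, 2) == expected

    def test_zero_events(self):
        summary = incidence_rate(0, 1000.0)
        assert summary.rate_per_1000py == 0.0
        assert summary.ci95_low == 0.0
        assert summary.ci95_high > 0.0

    def test_zero_person_years_rejected(self):
        with pytest.raises(EstimationError):
            incidence_rate(5, 0.0)

    def test_exact_ci_has_nominal_coverage(self):
        """Exact (chi-square) Poisson intervals cover the true rate in at
        least 95% of simulated draws (they are conservative)."""
        rng = np.random.default_rng(0)
        lam, py = 7.0, 1.0
        draws = rng.poisson(lam, 3000)
        cover = 0
        for k in draws:
            s = incidence_rate(int(k), py)
            cover += s.ci95_low <= lam * 1000 <= s.ci95_high
        assert cover / 3000 >= 0.945


class TestPoissonIRR:
    def test_equal_rates(self):
        est = poisson_irr(50, 1000.0, 50, 1000.0)
        assert est.rr == pytest.approx(1.0)
        assert est.p_value == pytest.approx(1.0)

    def test_published_cells_give_printed_ratio(self):
        est = poisson_irr(827, 136_523.0, 442, 90_381.0)
        assert round(est.rr, 2) == 1.24

    def test_zero_events_not_estimable(self):
        est = poisson_irr(0, 100.0, 5, 100.0)
        assert not est.estimable
        assert np.isnan(est.rr)

    def test_zero_person_time_rejected(self):
        with pytest.raises(EstimationError):
            poisson_irr(1, 0.0, 1, 10.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_equals_poisson_regression_with_offset(self, seed):
        """Closed form equals a GLM fit with arm indicator and log-py offset."""
        import statsmodels.api as sm

        rng = np.random.default_rng(seed)
        events = rng.integers(1, 200, 2)
        py = rng.uniform(50, 5000, 2)
        est = poisson_irr(int(events[0]), py[0], int(events[1]), py[1])
        glm = sm.GLM(
            events,
            sm.add_constant(np.array([1.0, 0.0])),
            family=sm.families.Poisson(),
            offset=np.log(py),
        ).fit()
        assert est.log_rr == pytest.approx(glm.params[1], abs=1e-6)
        assert est.se == pytest.approx(glm.bse[1], abs=1e-6)


class TestDifferences:
    def test_equal_rates_zero(self):
        r = incidence_rate(50, 10_000.0)
        ird, lo, hi = rate_difference(r, r)
        assert ird == 0.0 and lo < 0 < hi

    def test_printed_rates_difference(self):
        ird, _, _ = rate_difference(incidence_rate(827, 136_523.0), incidence_rate(442, 90_381.0))
        assert round(ird, 2) == 1.17

    def test_ard_from_printed_rates(self):
        # evaluated from the table's rounded rates, as a reader would
        t = RateSummary(827, 136_523.0, 6.06, 0, 0)
        c = RateSummary(442, 90_381.0, 4.89, 0, 0)
        ard, _, _ = absolute_risk_difference(t, c)
        assert ard == pytest.approx(8.96, abs=0.02)

    def test_tiny_rates_first_order_limit(self):
        t = RateSummary(2, 2_000_000.0, 0.001, 0, 0)
        c = RateSummary(1, 2_000_000.0, 0.0005, 0, 0)
        ard, _, _ = absolute_risk_difference(t, c)
        ird = 0.001 - 0.0005
        assert ard == pytest.approx(ird * (28 / 365.25) * 100, rel=1e-3)


class TestMDRR:
    def test_more_person_time_lowers_mdrr(self):
        a = mdrr(10_000.0, 10_000.0, 100)
        b = mdrr(20_000.0, 20_000.0, 200)
        assert b.mdrr < a.mdrr

    def test_large_counts_approach_one(self):
        d = mdrr(1_000_000.0, 1_000_000.0, 20_000)
        assert 1.0 < d.mdrr < 1.1

    def test_zero_events_not_estimable(self):
        d = mdrr(1000.0, 1000.0, 0)
        assert not d.estimable
        assert not d.passed

    def test_gate_threshold(self):
        d = mdrr(50.0, 50.0, 2)
        assert d.mdrr > 5
        assert not d.passed

    def test_satisfies_defining_equation(self):
        d = mdrr(10_000.0, 10_000.0, 100)
        r = 100 / 20_000.0
        z = stats.norm.ppf(0.975) + stats.norm.ppf(0.80)
        theta = d.mdrr
        se = np.sqrt(1 / (theta * r * 10_000) + 1 / (r * 10_000))
        assert np.log(theta) == pytest.approx(z * se, abs=1e-4)


class TestStratified:
    def _cohorts(self, cohort_of):
        t = cohort_of([(i, 0, 28) for i in range(1, 41)], arm="target")
        c = cohort_of([(i, 0, 28) for i in range(101, 141)], arm="comparator")
        ev_t = pd.Series(np.nan, index=pd.Index(t["person_id"], name="person_id"))
        ev_c = pd.Series(np.nan, index=pd.Index(c["person_id"], name="person_id"))
        ev_t.iloc[:8] = 10.0
        ev_c.iloc[:4] = 12.0
        return t, c, ev_t, ev_c

    def test_single_stratum_equals_unstratified(self, cohort_of):
        t, c, ev_t, ev_c = self._cohorts(cohort_of)
        age = pd.Series(45.0, index=range(40))
        sex = pd.Series("female", index=range(40))
        rows = stratified_estimates(t, c, ev_t, ev_c, age, age, sex, sex, mdrr_threshold=50)
        assert len(rows) == 1
        flat = estimate_cell(t, c, ev_t, ev_c)
        assert rows.loc[0, "rr"] == pytest.approx(flat.effect.rr)

    def test_event_counts_partition(self, cohort_of):
        t, c, ev_t, ev_c = self._cohorts(cohort_of)
        rng = np.random.default_rng(0)
        age_t = pd.Series(rng.choice([35.0, 55.0], 40))
        sex_t = pd.Series(rng.choice(["female", "male"], 40))
        rows = stratified_estimates(t, c, ev_t, ev_c, age_t, age_t, sex_t, sex_t, mdrr_threshold=50)
        counted = rows.dropna(subset=["events_target"]) if "events_target" in rows else rows
        assert counted["events_target"].sum() == 8
        assert counted["events_comparator"].sum() == 4

    def test_underpowered_stratum_suppressed(self, cohort_of):
        t, c, ev_t, ev_c = self._cohorts(cohort_of)
        age = pd.Series(45.0, index=range(40))
        sex = pd.Series("female", index=range(40))
        rows = stratified_estimates(t, c, ev_t, ev_c, age, age, sex, sex, mdrr_threshold=1.5)
        assert rows.loc[0, "status"] == "suppressed_power"
        assert np.isnan(rows.loc[0, "rr"])
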