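"""Incidence rates, Poisson rate ratios, rate and risk differences, and the
minimum detectable rate ratio (MDRR) power diagnostic.

Conventions: person-time is censored at the first event for the outcome under
analysis; 365.25 days per year; exact (chi-square) Poisson confidence
intervals for rates; Wald intervals for ratios. An arm with zero events makes
the ratio not estimable (no continuity correction) — such cells are
suppressed rather than corrected.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .config import DAYS_PER_YEAR
from .errors import EstimationError

Z975 = float(stats.norm.ppf(0.975))


@dataclass
class RateSummary:
    events: int
    person_years: float
    rate_per_1000py: float
    ci95_low: float
    ci95_high: float


@dataclass
class EffectEstimate:
    log_rr: float
    se: float
    rr: float
    ci95_low: float
    ci95_high: float
    p_value: float
    events_target: int
    py_target: float
    events_comparator: int
    py_comparator: float
    estimable: bool = True

    @classmethod
    def not_estimable(cls, events_t: int, py_t: float, events_c: int, py_c: float) -> "EffectEstimate":
        return cls(np.nan, np.nan, np.nan, np.nan, np.nan, np.nan, events_t, py_t, events_c, py_c, False)


@dataclass
class PowerDiagnostic:
    mdrr: float
    alpha: float = 0.05
    power: float = 0.80
    threshold: float = 5.0

    @property
    def estimable(self) -> bool:
        return np.isfinite(self.mdrr)

    @property
    def passed(self) -> bool:
        return self.estimable and self.mdrr <= self.threshold


def person_time(cohort: pd.DataFrame, event_days: pd.Series | None = None) -> pd.Series:
    """Person-years per entry: (min(event_day, follow_up_end) - index)/365.25.

    ``event_days`` is a person_id-indexed series (NaN = no event); time at
    risk ends at the first event for the outcome under analysis.
    """
    end = cohort["follow_up_end_day"].to_numpy(dtype=float)
    if event_days is not None:
        ev = event_days.reindex(cohort["person_id"]).to_numpy(dtype=float)
        end = np.fmin(end, ev)
    days = end - cohort["index_day"].to_numpy(dtype=float)
    if (days < 0).any():
        raise EstimationError("negative person-time interval")
    return pd.Series(days / DAYS_PER_YEAR, index=pd.Index(cohort["person_id"], name="person_id"))


def incidence_rate(events: int, person_years: float) -> RateSummary:
    """Events per 1000 person-years with an exact Poisson 95% CI."""
    if person_years <= 0:
        raise EstimationError("zero person-years: rate undefined")
    rate = events / person_years * 1000.0
    low = 0.0 if events == 0 else stats.chi2.ppf(0.025, 2 * events) / 2 / person_years * 1000.0
    high = stats.chi2.ppf(0.975, 2 * (events + 1)) / 2 / person_years * 1000.0
    return RateSummary(int(events), person_years, rate, low, high)


def poisson_irr(events_t: int, py_t: float, events_c: int, py_c: float) -> EffectEstimate:
    """Closed-form Poisson incidence rate ratio with Wald CI and p-value.

    Equals the arm-indicator Poisson regression with log person-time offset.
    """
    if py_t <= 0 or py_c <= 0:
        raise EstimationError("zero person-time in an arm")
    if events_t == 0 or events_c == 0:
        return EffectEstimate.not_estimable(events_t, py_t, events_c, py_c)
    theta = float(np.log((events_t / py_t) / (events_c / py_c)))
    se = float(np.sqrt(1.0 / events_t + 1.0 / events_c))
    z = theta / se
    p = float(2 * stats.norm.sf(abs(z)))
    return EffectEstimate(
        theta, se, float(np.exp(theta)),
        float(np.exp(theta - Z975 * se)), float(np.exp(theta + Z975 * se)),
        p, int(events_t), py_t, int(events_c), py_c,
    )


def rate_difference(rate_t: RateSummary, rate_c: RateSummary) -> tuple[float, float, float]:
    """Incidence rate difference per 1000 person-years with Wald 95% CI."""
    delta = rate_t.rate_per_1000py - rate_c.rate_per_1000py
    se = np.sqrt(
        rate_t.events / rate_t.person_years**2 + rate_c.events / rate_c.person_years**2
    ) * 1000.0
    return float(delta), float(delta - Z975 * se), float(delta + Z975 * se)


def absolute_risk_difference(
    rate_t: RateSummary, rate_c: RateSummary, window_days: int = 28
) -> tuple[float, float, float]:
    """28-day absolute risk difference per 100 000 vaccinated, delta-method CI.

    Per-arm cumulative risk is 1 - exp(-rate * window) under a constant
    hazard over the risk window.
    """
    t = window_days / DAYS_PER_YEAR

    def _risk(rate: RateSummary) -> tuple[float, float]:
        lam = rate.rate_per_1000py / 1000.0
        risk = 1.0 - np.exp(-lam * t)
        # d(risk)/d(lam) = t * exp(-lam t); Var(lam) = events / py^2
        var = (t * np.exp(-lam * t)) ** 2 * rate.events / rate.person_years**2
        return risk, var

    r_t, v_t = _risk(rate_t)
    r_c, v_c = _risk(rate_c)
    ard = (r_t - r_c) * 1e5
    se = np.sqrt(v_t + v_c) * 1e5
    return float(ard), float(ard - Z975 * se), float(ard + Z975 * se)


def mdrr(
    py_t: float,
    py_c: float,
    total_events: int,
    alpha: float = 0.05,
    power: float = 0.80,
    threshold: float = 5.0,
) -> PowerDiagnostic:
    """Minimum detectable rate ratio at the given alpha and power.

    The shared baseline rate is estimated as total events over total
    person-time; the MDRR is the smallest theta > 1 for which the Wald test
    on expected counts E_c = r*py_c, E_t = theta*r*py_t reaches the target
    power: log(theta) >= (z_{1-alpha/2} + z_power) * sqrt(1/E_t + 1/E_c).
    Solved by bisection to 1e-6; not estimable with zero events.
    """
    if py_t <= 0 or py_c <= 0:
        raise EstimationError("zero person-time in an arm")
    if total_events <= 0:
        return PowerDiagnostic(np.inf, alpha, power, threshold)
    r = total_events / (py_t + py_c)
    z = stats.norm.ppf(1 - alpha / 2) + stats.norm.ppf(power)

    def short(theta: float) -> float:
        se = np.sqrt(1.0 / (theta * r * py_t) + 1.0 / (r * py_c))
        return np.log(theta) - z * se

    lo, hi = 1.0 + 1e-9, 2.0
    while short(hi) < 0:
        hi *= 2.0
        if hi > 1e8:
            return PowerDiagnostic(np.inf, alpha, power, threshold)
    while hi - lo > 1e-6:
        mid = 0.5 * (lo + hi)
        if short(mid) >= 0:
            hi = mid
        else:
            lo = mid
    return PowerDiagnostic(0.5 * (lo + hi), alpha, power, threshold)


@dataclass
class CellEstimate:
    """All the pieces of one (outcome, stratum) comparison cell."""

    rate_target: RateSummary
    rate_comparator: RateSummary
    effect: EffectEstimate
    power: PowerDiagnostic


def estimate_cell(
    cohort_t: pd.DataFrame,
    cohort_c: pd.DataFrame,
    event_days_t: pd.Series,
    event_days_c: pd.Series,
    alpha: float = 0.05,
    power: float = 0.80,
    mdrr_threshold: float = 5.0,
) -> CellEstimate:
    """Estimation chain for one comparison cell from cohorts and event days."""
    pt_t = float(person_time(cohort_t, event_days_t).sum())
    pt_c = float(person_time(cohort_c, event_days_c).sum())
    ev_t = int(event_days_t.notna().sum())
    ev_c = int(event_days_c.notna().sum())
    rate_t = incidence_rate(ev_t, pt_t)
    rate_c = incidence_rate(ev_c, pt_c)
    effect = poisson_irr(ev_t, pt_t, ev_c, pt_c)
    pw = mdrr(pt_t, pt_c, ev_t + ev_c, alpha, power, mdrr_threshold)
    return CellEstimate(rate_t, rate_c, effect, pw)


def stratified_estimates(
    cohort_t: pd.DataFrame,
    cohort_c: pd.DataFrame,
    event_days_t: pd.Series,
    event_days_c: pd.Series,
    age_t: pd.Series,
    age_c: pd.Series,
    sex_t: pd.Series,
    sex_c: pd.Series,
    mdrr_threshold: float = 5.0,
) -> pd.DataFrame:
    """Estimation chain per 10-year age band x sex stratum.

    Strata whose MDRR exceeds the threshold (or with an empty arm) are
    suppressed with a reason, mirroring the power gate used for reporting.
    Returns one row per stratum with cells, estimates and status.
    """
    def bands(age: pd.Series) -> pd.Series:
        b = (np.floor(age / 10) * 10).astype(int)
        return b.astype(str) + "-" + (b + 9).astype(str)

    rows = []
    strata_t = bands(age_t) + "|" + sex_t.astype(str)
    strata_c = bands(age_c) + "|" + sex_c.astype(str)
    for stratum in sorted(set(strata_t) | set(strata_c)):
        sel_t = cohort_t[strata_t.to_numpy() == stratum]
        sel_c = cohort_c[strata_c.to_numpy() == stratum]
        if sel_t.empty or sel_c.empty:
            rows.append({"stratum": stratum, "status": "suppressed_empty"})
            continue
        cell = estimate_cell(
            sel_t, sel_c,
            event_days_t.loc[event_days_t.index.isin(sel_t["person_id"])],
            event_days_c.loc[event_days_c.index.isin(sel_c["person_id"])],
            mdrr_threshold=mdrr_threshold,
        )
        status = "reported"
        if not cell.power.passed:
            status = "suppressed_power"
        elif not cell.effect.estimable:
            status = "not_estimable"
        rows.append(
            {
                "stratum": stratum,
                "status": status,
                "events_target": cell.effect.events_target,
                "py_target": cell.effect.py_target,
                "events_comparator": cell.effect.events_comparator,
                "py_comparator": cell.effect.py_comparator,
                "rr": cell.effect.rr if status == "reported" else np.nan,
                "ci95_low": cell.effect.ci95_low if status == "reported" else np.nan,
                "ci95_high": cell.effect.ci95_high if status == "reported" else np.nan,
                "mdrr": cell.power.mdrr,
            }
        )
    return pd.DataFrame(rows)
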