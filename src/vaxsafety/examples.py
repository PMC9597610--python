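"""Worked-example inputs: published event-count and person-year cells.

These are aggregate cells of the kind printed in database-specific results
tables of multinational covid-19 vaccine-safety studies comparing adenovirus
with mRNA vaccines (matched-cohort thrombocytopenia analyses). They are data
inputs for exercising the rate, ratio and difference arithmetic on realistic
magnitudes — no patient-level information is involved.

Each cell is (events, person_years); rates print per 1000 person-years.
"""
from __future__ import annotations

from .estimation import (
    EffectEstimate,
    RateSummary,
    absolute_risk_difference,
    incidence_rate,
    poisson_irr,
)

#: Thrombocytopenia after first-dose adenovirus vs mRNA vaccination,
#: matched cohorts, one UK and one German database. Keys: (database, arm).
THROMBOCYTOPENIA_CELLS: dict[tuple[str, str], tuple[int, float]] = {
    ("uk_primary_care", "target"): (827, 136_523.0),
    ("uk_primary_care", "comparator"): (442, 90_381.0),
    ("germany_ambulatory", "target"): (35, 6_234.0),
    ("germany_ambulatory", "comparator"): (78, 15_516.0),
}

#: Single-dose adenovirus arm of a Spanish matched thrombocytopenia analysis.
SPAIN_AD26_THROMBOCYTOPENIA: tuple[int, float] = (49, 5_037.0)


def worked_example_rates() -> dict[str, RateSummary]:
    """Incidence rates per 1000 person-years for every example cell."""
    out = {
        f"{db}_{arm}": incidence_rate(events, py)
        for (db, arm), (events, py) in THROMBOCYTOPENIA_CELLS.items()
    }
    out["spain_ad26"] = incidence_rate(*SPAIN_AD26_THROMBOCYTOPENIA)
    return out


def worked_example_irr(database: str = "uk_primary_care") -> EffectEstimate:
    """Uncalibrated Poisson IRR from the target and comparator cells."""
    ev_t, py_t = THROMBOCYTOPENIA_CELLS[(database, "target")]
    ev_c, py_c = THROMBOCYTOPENIA_CELLS[(database, "comparator")]
    return poisson_irr(ev_t, py_t, ev_c, py_c)


def worked_example_event_totals() -> tuple[int, int]:
    """Total thrombocytopenia events across databases (target, comparator)."""
    target = sum(ev for (db, arm), (ev, _) in THROMBOCYTOPENIA_CELLS.items() if arm == "target")
    comparator = sum(ev for (db, arm), (ev, _) in THROMBOCYTOPENIA_CELLS.items() if arm == "comparator")
    return target, comparator


def worked_example_differences(decimals: int = 2) -> dict[str, float]:
    """IRD per 1000 py and 28-day ARD per 100 000, from the UK cells.

    The ARD is evaluated from the printed (rounded) rates, as it would be by
    a reader reproducing the arithmetic from a results table.
    """
    rates = worked_example_rates()
    r_t = rates["uk_primary_care_target"]
    r_c = rates["uk_primary_care_comparator"]
    ird = r_t.rate_per_1000py - r_c.rate_per_1000py
    rounded_t = RateSummary(r_t.events, r_t.person_years, round(r_t.rate_per_1000py, decimals), 0, 0)
    rounded_c = RateSummary(r_c.events, r_c.person_years, round(r_c.rate_per_1000py, decimals), 0, 0)
    ard, _, _ = absolute_risk_difference(rounded_t, rounded_c)
    return {"ird_per_1000py": float(ird), "ard_per_100k": float(ard)}
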