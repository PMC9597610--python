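"""Brand- and dose-specific vaccination cohorts and baseline covariates.

Eligibility mirrors routine vaccine-safety practice: adults at first dose, at
least a year of database history before index, a recorded brand, complete
age/sex, and exclusion of people whose two doses are 14 days or fewer apart
(likely recording errors). Follow-up runs from the index vaccination to 28
days, death, or end of observation, whichever comes first.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse

from .config import BRANDS, UNKNOWN_BRAND, calendar_month, calendar_year
from .errors import CohortError, ConfigValidationError, UnknownBrandError
from .synthetic import SyntheticDatabase

COHORT_COLUMNS = ["person_id", "arm", "index_day", "follow_up_end_day", "censor_reason"]


@dataclass
class EligibilityRules:
    min_age_years: int = 18
    min_prior_history_days: int = 365
    min_dose_gap_days: int = 14  # exclude persons with gap <= this
    require_known_brand: bool = True
    require_complete_age_sex: bool = True

    def __post_init__(self) -> None:
        for name in ("min_age_years", "min_prior_history_days", "min_dose_gap_days"):
            if getattr(self, name) < 0:
                raise ConfigValidationError(f"{name} must be non-negative")


def build_cohort(
    db: SyntheticDatabase,
    brand: str,
    dose_number: int,
    rules: EligibilityRules | None = None,
    risk_window_days: int = 28,
    arm: str = "target",
    study_start_year: int = 2021,
) -> pd.DataFrame:
    """Build the cohort of eligible recipients of ``brand`` dose ``dose_number``.

    Returns a DataFrame with columns person_id, arm, index_day,
    follow_up_end_day, censor_reason (window_end/death/observation_end). The
    index date is the day of the defining dose; age is evaluated at dose 1.
    """
    rules = rules or EligibilityRules()
    if brand not in BRANDS:
        raise UnknownBrandError(f"unknown brand label {brand!r}; known: {BRANDS}")
    if dose_number not in (1, 2):
        raise CohortError(f"dose_number must be 1 or 2, got {dose_number!r}")

    vacc = db.vaccinations
    d1 = vacc[vacc["dose_number"] == 1].set_index("person_id")
    d2 = vacc[vacc["dose_number"] == 2].set_index("person_id")

    defining = vacc[(vacc["dose_number"] == dose_number) & (vacc["brand"] == brand)]
    cohort = defining.merge(db.persons, on="person_id", how="left")
    if cohort.empty:
        return pd.DataFrame(columns=COHORT_COLUMNS)

    cohort = cohort.join(d1[["day", "brand"]].rename(columns={"day": "d1_day", "brand": "d1_brand"}), on="person_id")
    cohort = cohort.join(d2[["day", "brand"]].rename(columns={"day": "d2_day", "brand": "d2_brand"}), on="person_id")

    keep = pd.Series(True, index=cohort.index)

    if rules.require_complete_age_sex:
        keep &= cohort["birth_year"].notna() & cohort["sex"].notna()

    # Age >= 18 at the first dose.
    d1_year = calendar_year(cohort["d1_day"].fillna(cohort["day"]).to_numpy(), study_start_year)
    age_at_d1 = d1_year - cohort["birth_year"].to_numpy()
    with np.errstate(invalid="ignore"):
        keep &= pd.Series(age_at_d1 >= rules.min_age_years, index=cohort.index).fillna(False)

    # At least a year of history before the index date.
    keep &= (cohort["day"] - cohort["observation_start_day"]) >= rules.min_prior_history_days

    # Index vaccination must fall inside the observation period.
    keep &= (cohort["day"] >= cohort["observation_start_day"]) & (cohort["day"] <= cohort["observation_end_day"])

    if rules.require_known_brand:
        unknown_any = (cohort["d1_brand"] == UNKNOWN_BRAND) | (
            cohort["d2_brand"].notna() & (cohort["d2_brand"] == UNKNOWN_BRAND)
        )
        keep &= ~unknown_any.fillna(False)

    # Persons whose two doses are <= 14 days apart are excluded entirely.
    has_both = cohort["d1_day"].notna() & cohort["d2_day"].notna()
    gap = cohort["d2_day"] - cohort["d1_day"]
    keep &= ~(has_both & (gap <= rules.min_dose_gap_days))

    if dose_number == 2:
        keep &= (cohort["d1_brand"] == brand).fillna(False)

    cohort = cohort[keep].copy()
    index_day = cohort["day"].to_numpy(dtype=np.int64)
    window_end = index_day + risk_window_days
    death = cohort["death_day"].to_numpy(dtype=float)
    obs_end = cohort["observation_end_day"].to_numpy(dtype=np.int64)
    death_filled = np.where(np.isnan(death), np.inf, death)
    fu_end = np.minimum(window_end, np.minimum(death_filled, obs_end)).astype(np.int64)
    reason = np.where(
        fu_end == window_end,
        "window_end",
        np.where(fu_end == death_filled, "death", "observation_end"),
    )
    out = pd.DataFrame(
        {
            "person_id": cohort["person_id"].to_numpy(),
            "arm": arm,
            "index_day": index_day,
            "follow_up_end_day": fu_end,
            "censor_reason": reason,
        }
    )
    return out.sort_values("person_id", kind="stable").reset_index(drop=True)


def subsample_cohort(cohort: pd.DataFrame, fraction: float, seed: int) -> pd.DataFrame:
    """Random sample of round(fraction * n) entries, deterministic under seed."""
    if not 0 < fraction <= 1:
        raise CohortError(f"fraction must be in (0, 1], got {fraction!r}")
    if fraction == 1:
        return cohort.copy()
    n = len(cohort)
    k = int(round(fraction * n))
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(n, size=k, replace=False))
    return cohort.iloc[idx].reset_index(drop=True)


@dataclass
class CovariateExtractionSpec:
    """Which covariates to extract at the cohort index date."""

    condition_concepts: tuple[str, ...] = (
        "hypertension",
        "diabetes",
        "cancer",
        "heart_failure",
        "vascular_disease",
        "stroke_history",
    )
    utilisation_concepts: tuple[str, ...] = ("drug_record", "procedure_record", "measurement_record")
    utilisation_lookback_days: int = 180
    study_start_year: int = 2021
    include_scores: bool = True


@dataclass
class CovariateMatrix:
    """Sparse person-by-covariate matrix with metadata.

    ``meta`` has one row per column: covariate_id, label, kind
    (continuous/binary/count). Row order follows ``person_ids``.
    """

    matrix: sparse.csr_matrix
    meta: pd.DataFrame
    person_ids: np.ndarray

    def column(self, label: str) -> np.ndarray:
        j = self.meta.index[self.meta["label"] == label]
        if len(j) == 0:
            raise KeyError(label)
        return np.asarray(self.matrix[:, int(j[0])].todense()).ravel()

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix.toarray(), columns=list(self.meta["label"]), index=self.person_ids)


@dataclass
class ScoreDefinition:
    """A weighted-sum comorbidity score over condition flags.

    When ``age_sex_points`` is set, the standard stroke-risk-score extras are
    added: +1 for age 65-74, +2 for age >= 75, +1 for female sex.
    """

    name: str
    weights: dict[str, int] = field(default_factory=dict)
    age_sex_points: bool = False

    def __post_init__(self) -> None:
        for comp, w in self.weights.items():
            if w < 0:
                raise ConfigValidationError(f"score {self.name}: weight for {comp!r} must be >= 0")


#: Romano adaptation of the Charlson comorbidity index, restricted to the
#: condition concepts the generator emits.
ROMANO_CHARLSON = ScoreDefinition(
    "charlson_romano",
    weights={
        "heart_failure": 1,
        "vascular_disease": 1,
        "stroke_history": 1,
        "diabetes": 1,
        "cancer": 2,
    },
)

#: CHA2DS2-VASc stroke-risk score (congestive heart failure, hypertension,
#: age, diabetes, stroke, vascular disease, sex category).
CHA2DS2_VASC = ScoreDefinition(
    "cha2ds2_vasc",
    weights={
        "heart_failure": 1,
        "hypertension": 1,
        "diabetes": 1,
        "stroke_history": 2,
        "vascular_disease": 1,
    },
    age_sex_points=True,
)


def compute_score(
    flags: dict[str, int] | pd.Series,
    definition: ScoreDefinition,
    age: float,
    sex: str,
) -> int:
    """Weighted sum of present component flags, plus age/sex points if enabled.

    Components absent from ``flags`` count as 0.
    """
    total = 0
    for comp, w in definition.weights.items():
        total += w * int(bool(flags.get(comp, 0)))
    if definition.age_sex_points:
        if age >= 75:
            total += 2
        elif age >= 65:
            total += 1
        if sex == "female":
            total += 1
    return total


def extract_covariates(
    db: SyntheticDatabase,
    cohort: pd.DataFrame,
    spec: CovariateExtractionSpec | None = None,
) -> CovariateMatrix:
    """Baseline covariates for every cohort entry.

    Emits continuous age, 10-year age-band indicators, a female-sex
    indicator, index-year and index-month one-hot indicators, binary flags
    for each condition concept observed strictly before the index date, and
    counts of utilisation records in the 180 days before index (half-open
    window [index-180, index)). Optionally appends the two comorbidity
    scores.
    """
    spec = spec or CovariateExtractionSpec()
    persons = db.persons.set_index("person_id")
    missing = ~cohort["person_id"].isin(persons.index)
    if missing.any():
        raise CohortError(f"person_id {int(cohort.loc[missing.idxmax(), 'person_id'])} missing from database")
    n = len(cohort)
    pid = cohort["person_id"].to_numpy()
    pinfo = persons.loc[pid]
    index_day = cohort["index_day"].to_numpy()

    year = calendar_year(index_day, spec.study_start_year)
    month = calendar_month(index_day)
    age = year - pinfo["birth_year"].to_numpy(dtype=float)
    female = (pinfo["sex"] == "female").to_numpy(dtype=float)

    columns: list[tuple[str, str, np.ndarray]] = [("age", "continuous", age)]
    bands = np.unique((np.floor(age / 10) * 10).astype(int))
    for band in bands:
        columns.append((f"age_band_{band}_{band + 9}", "binary", ((age >= band) & (age < band + 10)).astype(float)))
    columns.append(("sex_female", "binary", female))
    for y in np.unique(year):
        columns.append((f"index_year_{y}", "binary", (year == y).astype(float)))
    for m in np.unique(month):
        columns.append((f"index_month_{int(m):02d}", "binary", (month == m).astype(float)))

    events = db.events
    order = pd.Series(np.arange(n), index=pid)
    relevant = events[events["concept"].isin(set(spec.condition_concepts) | set(spec.utilisation_concepts))]
    merged = relevant.merge(cohort[["person_id", "index_day"]], on="person_id", how="inner")

    cond_flags: dict[str, np.ndarray] = {}
    for concept in spec.condition_concepts:
        sub = merged[(merged["concept"] == concept) & (merged["day"] < merged["index_day"])]
        flag = np.zeros(n)
        if len(sub):
            rows = order.loc[sub["person_id"].unique()].to_numpy()
            flag[rows] = 1.0
        cond_flags[concept] = flag
        columns.append((f"condition_{concept}", "binary", flag))

    for concept in spec.utilisation_concepts:
        sub = merged[
            (merged["concept"] == concept)
            & (merged["day"] < merged["index_day"])
            & (merged["day"] >= merged["index_day"] - spec.utilisation_lookback_days)
        ]
        counts = np.zeros(n)
        if len(sub):
            grouped = sub.groupby("person_id").size()
            counts[order.loc[grouped.index].to_numpy()] = grouped.to_numpy(dtype=float)
        columns.append((f"count_{concept}", "count", counts))

    if spec.include_scores:
        for definition in (ROMANO_CHARLSON, CHA2DS2_VASC):
            score = np.zeros(n)
            for comp, w in definition.weights.items():
                if comp in cond_flags:
                    score += w * cond_flags[comp]
            if definition.age_sex_points:
                score += np.where(age >= 75, 2, np.where(age >= 65, 1, 0))
                score += female
            columns.append((f"score_{definition.name}", "count", score))

    labels = [c[0] for c in columns]
    kinds = [c[1] for c in columns]
    dense = np.column_stack([c[2] for c in columns])
    meta = pd.DataFrame({"covariate_id": np.arange(len(labels)), "label": labels, "kind": kinds})
    return CovariateMatrix(sparse.csr_matrix(dense), meta, pid)
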