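"""Synthetic OMOP-flavoured two-arm vaccination databases with known truth.

The generator emits person, vaccination, clinical-event and platelet-
measurement tables whose statistical structure matches what the downstream
analysis assumes: brand assignment depends on measured covariates (creating
confounding when the same covariates carry outcome hazard ratios), outcomes
are rare Poisson processes with configurable true target-vs-comparator rate
ratios inside the post-vaccination risk window, negative controls have true
rate ratio 1, and an optional multiplicative ascertainment bias — drawn once
per outcome on the log scale — inflates or deflates event capture in the
target arm across every outcome.

Ground truth (true rate ratios, drawn bias multipliers, per-person assignment
probabilities) travels with the database so parameter recovery is testable.
"""
from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import (
    DAYS_PER_YEAR,
    BRANDS,
    UNKNOWN_BRAND,
    SimulationConfig,
)
from .errors import TableParseError

PERSON_COLUMNS = ["person_id", "sex", "birth_year", "observation_start_day", "observation_end_day", "death_day"]
VACCINATION_COLUMNS = ["person_id", "brand", "dose_number", "day"]
EVENT_COLUMNS = ["person_id", "concept", "day"]
MEASUREMENT_COLUMNS = ["person_id", "day", "value"]


@dataclass
class GroundTruth:
    """Generating parameters recorded alongside a synthetic database.

    ``outcomes`` has one row per outcome (negative controls included) with the
    true rate ratio and the realised target-arm bias multiplier;
    ``assignment_probability`` holds each person's true probability of
    receiving the target brand.
    """

    outcomes: pd.DataFrame  # outcome, true_rr, bias_multiplier, is_negative_control
    assignment_probability: pd.DataFrame  # person_id, p_target
    error_mean: float = 0.0
    error_sd: float = 0.0

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GroundTruth):
            return NotImplemented
        return (
            self.outcomes.reset_index(drop=True).equals(other.outcomes.reset_index(drop=True))
            and self.assignment_probability.reset_index(drop=True).equals(
                other.assignment_probability.reset_index(drop=True)
            )
            and self.error_mean == other.error_mean
            and self.error_sd == other.error_sd
        )


@dataclass
class SyntheticDatabase:
    """Bundle of the four record tables plus optional ground truth."""

    persons: pd.DataFrame
    vaccinations: pd.DataFrame
    events: pd.DataFrame
    measurements: pd.DataFrame
    ground_truth: GroundTruth | None = None

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SyntheticDatabase):
            return NotImplemented
        for name in ("persons", "vaccinations", "events", "measurements"):
            if not getattr(self, name).reset_index(drop=True).equals(
                getattr(other, name).reset_index(drop=True)
            ):
                return False
        return self.ground_truth == other.ground_truth


def _covariate_arrays(cfg: SimulationConfig, rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Draw per-person covariates used by both assignment and outcome hazards."""
    n = cfg.n_persons
    spec = cfg.covariate_spec
    age = np.clip(
        np.round(rng.normal(spec.age_mean, spec.age_sd, n)), spec.age_min, spec.age_max
    ).astype(int)
    female = (rng.random(n) < spec.p_female).astype(int)
    cov: dict[str, np.ndarray] = {
        "age": age.astype(float),
        "age_decade": (age - 50.0) / 10.0,
        "sex_female": female.astype(float),
    }
    for name, prev in spec.comorbidity_prevalence.items():
        cov[name] = (rng.random(n) < prev).astype(float)
    for name, mean in spec.utilisation_means.items():
        cov[name] = rng.poisson(mean, n).astype(float)
    return cov


def _segment_events(
    rng: np.random.Generator,
    person_id: np.ndarray,
    seg_start: np.ndarray,
    seg_end: np.ndarray,
    day_rate: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Poisson events on integer days in the inclusive segment [start, end]."""
    length = np.maximum(0, seg_end - seg_start + 1)
    counts = rng.poisson(day_rate * length)
    counts[length == 0] = 0
    total = int(counts.sum())
    if total == 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    idx = np.repeat(np.arange(person_id.size), counts)
    days = seg_start[idx] + rng.integers(0, length[idx])
    return person_id[idx], days


def generate_database(config: SimulationConfig, seed: int | None = None) -> SyntheticDatabase:
    """Generate a deterministic synthetic database from ``config`` and ``seed``.

    Each person receives exactly one brand's first dose (target or
    comparator, by a logistic model on the covariates), a same-brand second
    dose with the configured probability, a Poisson event stream per outcome
    whose intensity in the risk window carries the outcome's true rate ratio
    in the target arm, and platelet measurements around thrombosis-type
    events. Identical ``(config, seed)`` yields byte-identical tables.
    """
    config.validate()
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)
    n = config.n_persons
    person_id = np.arange(1, n + 1, dtype=np.int64)

    cov = _covariate_arrays(config, rng)
    vax_day = rng.integers(config.study_start_day, config.study_start_day + config.rollout_days + 1, n)
    cov["index_day_100"] = vax_day / 100.0

    # Observation history: at least a year plus a long tail, with a small
    # fraction of recently registered persons to exercise the history rule.
    extra = rng.exponential(config.extra_history_mean_days, n)
    history = 365 + np.round(extra).astype(int)
    short = rng.random(n) < config.p_short_history
    history[short] = rng.integers(30, 330, int(short.sum()))
    obs_start = vax_day - history

    # Censoring measured from the index date so follow-up is well defined.
    horizon = config.study_end_day + 90
    censor_days = np.round(
        rng.exponential(DAYS_PER_YEAR / max(config.censoring_hazard_per_year, 1e-12), n)
    ).astype(np.int64)
    obs_end = np.minimum(vax_day + censor_days, horizon)
    censored_early = obs_end < horizon
    dies = censored_early & (rng.random(n) < config.death_fraction)
    death_day = np.where(dies, obs_end, np.nan)

    # Brand assignment: logistic in the covariates (measured confounding).
    linpred = np.full(n, config.assignment_intercept, dtype=float)
    for name, coef in config.assignment_coefficients.items():
        if name not in cov:
            raise KeyError(f"assignment coefficient references unknown covariate {name!r}")
        linpred += coef * cov[name]
    p_target = 1.0 / (1.0 + np.exp(-linpred))
    is_target = rng.random(n) < p_target
    brand1 = np.where(is_target, config.target_brand, config.comparator_brand)

    recorded_brand1 = brand1.copy().astype(object)
    unknown = rng.random(n) < config.p_unknown_brand
    recorded_brand1[unknown] = UNKNOWN_BRAND

    # Second doses: same brand unless the crossover flag injects mismatches;
    # a short-gap fraction exercises the likely-data-error exclusion.
    has_d2 = rng.random(n) < config.p_dose2
    gap = rng.integers(config.dose2_gap_min, config.dose2_gap_max + 1, n)
    short_gap = rng.random(n) < config.p_short_gap
    gap[short_gap] = rng.integers(3, 15, int(short_gap.sum()))
    d2_day = vax_day + gap
    has_d2 &= d2_day <= obs_end
    brand2 = recorded_brand1.copy()
    crossover = rng.random(n) < config.p_crossover
    other = np.where(is_target, config.comparator_brand, config.target_brand)
    brand2[crossover] = other[crossover]

    # Missing demographics (excluded by eligibility downstream).
    missing = rng.random(n) < config.p_missing_age_sex
    sex = np.where(cov["sex_female"] == 1, "female", "male").astype(object)
    index_year = config.study_start_year + (vax_day // int(DAYS_PER_YEAR))
    birth_year = (index_year - cov["age"]).astype(float)
    sex[missing] = None
    birth_year[missing] = np.nan

    persons = pd.DataFrame(
        {
            "person_id": person_id,
            "sex": pd.array(sex, dtype="string"),
            "birth_year": birth_year,
            "observation_start_day": obs_start.astype(np.int64),
            "observation_end_day": obs_end.astype(np.int64),
            "death_day": death_day,
        }
    )

    vax_frames = [
        pd.DataFrame(
            {
                "person_id": person_id,
                "brand": pd.array(recorded_brand1, dtype="string"),
                "dose_number": 1,
                "day": vax_day.astype(np.int64),
            }
        ),
        pd.DataFrame(
            {
                "person_id": person_id[has_d2],
                "brand": pd.array(brand2[has_d2], dtype="string"),
                "dose_number": 2,
                "day": d2_day[has_d2].astype(np.int64),
            }
        ),
    ]
    vaccinations = pd.concat(vax_frames, ignore_index=True)

    # --- clinical events ---------------------------------------------------
    event_pids: list[np.ndarray] = []
    event_concepts: list[np.ndarray] = []
    event_days: list[np.ndarray] = []

    def _emit(pids: np.ndarray, days: np.ndarray, concept: str) -> None:
        if pids.size:
            event_pids.append(pids)
            event_days.append(days)
            event_concepts.append(np.full(pids.size, concept, dtype=object))

    # Baseline comorbidity condition records strictly before index.
    for name in config.covariate_spec.comorbidity_prevalence:
        flag = cov[name] == 1
        pids = person_id[flag]
        lo, hi = obs_start[flag], vax_day[flag] - 1
        ok = hi >= lo
        days = lo[ok] + rng.integers(0, hi[ok] - lo[ok] + 1)
        _emit(pids[ok], days, name)

    # Utilisation records in the six months before index.
    for name in config.covariate_spec.utilisation_means:
        counts = cov[name].astype(int)
        idx = np.repeat(np.arange(n), counts)
        lo = np.maximum(obs_start[idx], vax_day[idx] - 180)
        hi = vax_day[idx] - 1
        ok = hi >= lo
        days = lo[ok] + rng.integers(0, hi[ok] - lo[ok] + 1)
        _emit(person_id[idx][ok], days, name)

    # Outcome event streams (study outcomes then negative controls), each a
    # piecewise-constant Poisson process: baseline intensity everywhere, times
    # the true RR inside the risk window for the target arm, times the
    # outcome's realised ascertainment-bias multiplier in the target arm.
    err = config.systematic_error
    all_outcomes: list[tuple[str, float, dict[str, float], bool, bool]] = [
        (name, p.true_rr, p.covariate_log_hr, p.emit_platelets, False)
        for name, p in config.outcome_spec.items()
    ] + [
        (name, 1.0, config.nc_covariate_log_hr, False, True)
        for name in config.negative_control_names()
    ]
    truth_rows = []
    w = config.effect_window_days
    win_start = vax_day + 1
    win_end = np.minimum(vax_day + w, obs_end)
    thrombo_pids: list[np.ndarray] = []
    thrombo_days: list[np.ndarray] = []

    baselines = {name: config.outcome_spec[name].baseline_rate for name in config.outcome_spec}
    for name, true_rr, log_hr, emit_platelets, is_nc in all_outcomes:
        base = config.nc_baseline_rate if is_nc else baselines[name]
        bias = float(np.exp(rng.normal(err.mean, err.sd))) if (err.mean != 0.0 or err.sd != 0.0) else 1.0
        truth_rows.append((name, true_rr, bias, is_nc))
        mult = np.zeros(n)
        for covname, g in log_hr.items():
            mult += g * cov[covname]
        day_rate = base / DAYS_PER_YEAR * np.exp(mult)
        arm_mult = np.where(is_target, bias, 1.0)
        out_rate = day_rate * arm_mult
        in_rate = out_rate * np.where(is_target, true_rr, 1.0)
        # segment A: [obs_start, vax_day]; B: (vax_day, win_end]; C: (win_end, obs_end]
        p_a, d_a = _segment_events(rng, person_id, obs_start, vax_day, out_rate)
        p_b, d_b = _segment_events(rng, person_id, win_start, win_end, in_rate)
        p_c, d_c = _segment_events(rng, person_id, win_end + 1, obs_end, out_rate)
        for p_, d_ in ((p_a, d_a), (p_b, d_b), (p_c, d_c)):
            _emit(p_, d_, name)
            if emit_platelets and p_.size:
                thrombo_pids.append(p_)
                thrombo_days.append(d_)

    if event_pids:
        events = pd.DataFrame(
            {
                "person_id": np.concatenate(event_pids),
                "concept": pd.array(np.concatenate(event_concepts), dtype="string"),
                "day": np.concatenate(event_days).astype(np.int64),
            }
        )
        events = events.sort_values(["person_id", "day"], kind="stable").reset_index(drop=True)
    else:
        events = pd.DataFrame(
            {"person_id": pd.Series(dtype=np.int64), "concept": pd.Series(dtype="string"), "day": pd.Series(dtype=np.int64)}
        )

    # --- platelet measurements ---------------------------------------------
    ps = config.platelet_spec
    m_pids: list[np.ndarray] = []
    m_days: list[np.ndarray] = []
    m_vals: list[np.ndarray] = []
    if thrombo_pids:
        tp = np.concatenate(thrombo_pids)
        td = np.concatenate(thrombo_days)
        measured = rng.random(tp.size) < ps.p_measured_near_event
        tp, td = tp[measured], td[measured]
        offs = rng.integers(-ps.offset_days, ps.offset_days + 1, tp.size)
        mday = td + offs
        pos = tp - 1  # person_id is 1..n
        mday = np.clip(mday, obs_start[pos], obs_end[pos])
        low = rng.random(tp.size) < ps.p_low_given_measured
        vals = np.where(
            low,
            rng.normal(ps.low_mean, ps.low_sd, tp.size),
            rng.normal(ps.normal_mean, ps.normal_sd, tp.size),
        )
        vals = np.maximum(vals, ps.floor)
        m_pids.append(tp)
        m_days.append(mday)
        m_vals.append(vals)
    background = rng.random(n) < ps.background_probability
    if background.any():
        bp = person_id[background]
        lo, hi = obs_start[background], obs_end[background]
        bd = lo + rng.integers(0, hi - lo + 1)
        bv = np.maximum(rng.normal(ps.normal_mean, ps.normal_sd, bp.size), ps.floor)
        m_pids.append(bp)
        m_days.append(bd)
        m_vals.append(bv)
    if m_pids:
        measurements = pd.DataFrame(
            {
                "person_id": np.concatenate(m_pids),
                "day": np.concatenate(m_days).astype(np.int64),
                "value": np.concatenate(m_vals),
            }
        ).sort_values(["person_id", "day"], kind="stable").reset_index(drop=True)
    else:
        measurements = pd.DataFrame(
            {"person_id": pd.Series(dtype=np.int64), "day": pd.Series(dtype=np.int64), "value": pd.Series(dtype=float)}
        )

    truth = GroundTruth(
        outcomes=pd.DataFrame(
            truth_rows, columns=["outcome", "true_rr", "bias_multiplier", "is_negative_control"]
        ).astype({"outcome": "string"}),
        assignment_probability=pd.DataFrame({"person_id": person_id, "p_target": p_target}),
        error_mean=err.mean,
        error_sd=err.sd,
    )
    return SyntheticDatabase(persons, vaccinations, events, measurements, truth)


# --- delimited-table round trip --------------------------------------------

_TABLES = {
    "person.csv": PERSON_COLUMNS,
    "vaccination.csv": VACCINATION_COLUMNS,
    "event.csv": EVENT_COLUMNS,
    "measurement.csv": MEASUREMENT_COLUMNS,
}

_INT_COLUMNS = {
    "person.csv": ["person_id", "observation_start_day", "observation_end_day"],
    "vaccination.csv": ["person_id", "dose_number", "day"],
    "event.csv": ["person_id", "day"],
    "measurement.csv": ["person_id", "day"],
}

_STRING_COLUMNS = {"person.csv": ["sex"], "vaccination.csv": ["brand"], "event.csv": ["concept"]}

_FLOAT_COLUMNS = {"person.csv": ["birth_year", "death_day"], "measurement.csv": ["value"]}


def write_database(db: SyntheticDatabase, directory: str) -> list[str]:
    """Write one UTF-8 comma-separated table per record type; returns paths."""
    os.makedirs(directory, exist_ok=True)
    written = []
    frames = {
        "person.csv": db.persons,
        "vaccination.csv": db.vaccinations,
        "event.csv": db.events,
        "measurement.csv": db.measurements,
    }
    for name, frame in frames.items():
        path = os.path.join(directory, name)
        frame.to_csv(path, index=False, float_format="%.17g")
        written.append(path)
    if db.ground_truth is not None:
        gt = db.ground_truth
        out = gt.outcomes.copy()
        out["error_mean"] = gt.error_mean
        out["error_sd"] = gt.error_sd
        p1 = os.path.join(directory, "ground_truth.csv")
        out.to_csv(p1, index=False, float_format="%.17g")
        p2 = os.path.join(directory, "ground_truth_person.csv")
        gt.assignment_probability.to_csv(p2, index=False, float_format="%.17g")
        written += [p1, p2]
    return written


def _read_table(directory: str, name: str) -> pd.DataFrame:
    path = os.path.join(directory, name)
    if not os.path.exists(path):
        raise TableParseError(f"missing table file {name!r}", filename=name)
    dtypes = {c: "string" for c in _STRING_COLUMNS.get(name, [])}
    frame = pd.read_csv(path, dtype=dtypes, float_precision="round_trip")
    for col in _TABLES[name]:
        if col not in frame.columns:
            raise TableParseError(f"missing required column {col!r}", filename=name)
    for col in _INT_COLUMNS[name]:
        values = frame[col]
        numeric = pd.to_numeric(values, errors="coerce")
        bad = numeric.isna() | (numeric != np.floor(numeric.fillna(0)))
        if bad.any():
            line = int(bad.idxmax()) + 2  # header is line 1
            raise TableParseError(
                f"column {col!r} must be an integer day/count, got {values[bad].iloc[0]!r}",
                filename=name,
                line=line,
            )
        frame[col] = numeric.astype(np.int64)
    for col in _FLOAT_COLUMNS.get(name, []):
        frame[col] = pd.to_numeric(frame[col], errors="coerce").astype(float)
    return frame[_TABLES[name]]


def read_database(directory: str, validate: bool = True) -> SyntheticDatabase:
    """Read a database directory written by :func:`write_database`.

    Schema violations raise :class:`TableParseError` naming the file, line and
    the broken constraint. Ground-truth tables are optional.
    """
    persons = _read_table(directory, "person.csv")
    vaccinations = _read_table(directory, "vaccination.csv")
    events = _read_table(directory, "event.csv")
    measurements = _read_table(directory, "measurement.csv")

    if validate:
        dup = vaccinations.duplicated(subset=["person_id", "dose_number"])
        if dup.any():
            line = int(dup.idxmax()) + 2
            row = vaccinations.loc[dup.idxmax()]
            raise TableParseError(
                "at most one vaccination record per (person, dose): duplicate "
                f"(person_id={row['person_id']}, dose_number={row['dose_number']})",
                filename="vaccination.csv",
                line=line,
            )
        wide = vaccinations.pivot_table(index="person_id", columns="dose_number", values="day", aggfunc="first")
        if 1 in wide.columns and 2 in wide.columns:
            both = wide.dropna(subset=[1, 2])
            bad = both[both[2] <= both[1]]
            if len(bad):
                raise TableParseError(
                    f"dose 2 day must exceed dose 1 day for person_id={int(bad.index[0])}",
                    filename="vaccination.csv",
                )
        span = events.merge(persons[["person_id", "observation_start_day", "observation_end_day"]], on="person_id", how="left")
        outside = (
            span["observation_start_day"].isna()
            | (span["day"] < span["observation_start_day"])
            | (span["day"] > span["observation_end_day"])
        )
        if outside.any():
            line = int(outside.idxmax()) + 2
            raise TableParseError(
                "event day outside its person's observation period "
                f"(person_id={int(span.loc[outside.idxmax(), 'person_id'])})",
                filename="event.csv",
                line=line,
            )
        if (measurements["value"] <= 0).any():
            line = int((measurements["value"] <= 0).idxmax()) + 2
            raise TableParseError("platelet measurement value must be > 0", filename="measurement.csv", line=line)
        dd = persons["death_day"]
        bad_death = dd.notna() & (dd > persons["observation_end_day"])
        if bad_death.any():
            line = int(bad_death.idxmax()) + 2
            raise TableParseError("death_day must be <= observation_end_day", filename="person.csv", line=line)

    truth = None
    gt_path = os.path.join(directory, "ground_truth.csv")
    if os.path.exists(gt_path):
        out = pd.read_csv(gt_path, dtype={"outcome": "string"}, float_precision="round_trip")
        error_mean = float(out["error_mean"].iloc[0]) if len(out) else 0.0
        error_sd = float(out["error_sd"].iloc[0]) if len(out) else 0.0
        out = out[["outcome", "true_rr", "bias_multiplier", "is_negative_control"]].astype(
            {"true_rr": float, "bias_multiplier": float, "is_negative_control": bool}
        )
        pp_path = os.path.join(directory, "ground_truth_person.csv")
        if os.path.exists(pp_path):
            pp = pd.read_csv(pp_path, float_precision="round_trip").astype(
                {"person_id": np.int64, "p_target": float}
            )
        else:
            pp = pd.DataFrame(columns=["person_id", "p_target"])
        truth = GroundTruth(out, pp, error_mean, error_sd)
    return SyntheticDatabase(persons, vaccinations, events, measurements, truth)
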