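"""Configuration objects for the synthetic-database generator and helpers.

The calendar is an integer day index with day 0 = study start; no real dates
are used anywhere. ``calendar_year``/``calendar_month`` derive the index-year
and index-month covariates from the day index.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Any

import yaml

from .errors import ConfigValidationError

#: Vaccine brands of the four products compared in the study design this
#: pipeline implements: two adenovirus-vectored and two mRNA vaccines.
BRANDS = ("ChAdOx1-S", "BNT162b2", "mRNA-1273", "Ad26.COV2.S")

#: Brand label used for vaccination records with an unspecified product code.
UNKNOWN_BRAND = "unknown"

DAYS_PER_YEAR = 365.25


def calendar_year(day: int | Any, study_start_year: int = 2021) -> Any:
    """Calendar year containing ``day`` (day 0 = Jan 1 of the start year)."""
    import numpy as np

    return study_start_year + np.floor(np.asarray(day) / DAYS_PER_YEAR).astype(int)


def calendar_month(day: int | Any) -> Any:
    """Month-of-year (1..12) of ``day``, using equal 30.4375-day months."""
    import numpy as np

    day_in_year = np.mod(np.asarray(day), DAYS_PER_YEAR)
    return np.minimum(12, (day_in_year / (DAYS_PER_YEAR / 12)).astype(int) + 1)


@dataclass
class OutcomeParams:
    """Generating parameters for one outcome's Poisson event process.

    ``baseline_rate`` is in events per person-year; ``true_rr`` multiplies the
    hazard in the post-vaccination risk window for the target arm only.
    ``covariate_log_hr`` maps covariate names to log hazard ratios, making the
    assignment covariates genuine confounders. ``emit_platelets`` marks
    thrombosis-type outcomes around which platelet measurements are generated.
    """

    baseline_rate: float
    true_rr: float = 1.0
    covariate_log_hr: dict[str, float] = field(default_factory=dict)
    emit_platelets: bool = False


@dataclass
class PlateletSpec:
    """How platelet-count measurements (10^3 platelets/uL) are generated.

    Normal counts are centred at 250 (SD 50); low counts at 90 (SD 30),
    floored at 5, spanning both the 150 and 100 thrombocytopenia thresholds.
    """

    p_measured_near_event: float = 0.8
    p_low_given_measured: float = 0.3
    offset_days: int = 7
    normal_mean: float = 250.0
    normal_sd: float = 50.0
    low_mean: float = 90.0
    low_sd: float = 30.0
    floor: float = 5.0
    background_probability: float = 0.05


@dataclass
class CovariateSpec:
    """Marginal distributions of the baseline covariates."""

    age_mean: float = 52.0
    age_sd: float = 17.0
    age_min: int = 16
    age_max: int = 95
    p_female: float = 0.54
    comorbidity_prevalence: dict[str, float] = field(
        default_factory=lambda: {
            "hypertension": 0.25,
            "diabetes": 0.10,
            "cancer": 0.05,
            "heart_failure": 0.03,
            "vascular_disease": 0.06,
            "stroke_history": 0.02,
        }
    )
    utilisation_means: dict[str, float] = field(
        default_factory=lambda: {
            "drug_record": 3.0,
            "procedure_record": 1.2,
            "measurement_record": 2.0,
        }
    )


@dataclass
class SystematicErrorSpec:
    """Multiplicative ascertainment bias applied to the target arm.

    One multiplier per outcome is drawn as exp(Normal(mean, sd)) on the log
    scale and applied to that outcome's event intensity in the target arm for
    ALL outcomes, negative controls included. This is exactly the residual
    systematic error structure the empirical null models downstream.
    """

    mean: float = 0.0
    sd: float = 0.0


def _default_outcomes() -> dict[str, OutcomeParams]:
    # Baselines loosely track 28-day incidence in matched covid-19 vaccination
    # cohorts (a few events per 1000 person-years for thromboembolic events).
    age = {"age_decade": 0.35}
    return {
        "deep_vein_thrombosis": OutcomeParams(1.5e-3, 1.0, dict(age), True),
        "pulmonary_embolism": OutcomeParams(1.9e-3, 1.0, dict(age), True),
        "ischaemic_stroke": OutcomeParams(0.7e-3, 1.0, dict(age), True),
        "myocardial_infarction": OutcomeParams(2.0e-3, 1.0, dict(age), True),
        "thrombocytopenia": OutcomeParams(5.0e-3, 1.0, dict(age), False),
    }


@dataclass
class SimulationConfig:
    """Full parameterisation of one synthetic two-arm vaccination database.

    Rates are events per person-year; all times are integer day indices with
    day 0 = study start. ``assignment_coefficients`` are per-covariate
    log-odds of receiving the target brand, which creates measured
    confounding when the same covariates carry outcome hazard ratios.
    """

    n_persons: int = 20_000
    study_start_day: int = 0
    study_end_day: int = 240
    study_start_year: int = 2021
    brand_set: tuple[str, ...] = BRANDS
    target_brand: str = "ChAdOx1-S"
    comparator_brand: str = "BNT162b2"
    assignment_intercept: float = 0.0
    assignment_coefficients: dict[str, float] = field(default_factory=dict)
    covariate_spec: CovariateSpec = field(default_factory=CovariateSpec)
    outcome_spec: dict[str, OutcomeParams] = field(default_factory=_default_outcomes)
    n_negative_controls: int = 40
    nc_baseline_rate: float = 0.02
    nc_covariate_log_hr: dict[str, float] = field(
        default_factory=lambda: {"age_decade": 0.15, "sex_female": 0.10}
    )
    systematic_error: SystematicErrorSpec = field(default_factory=SystematicErrorSpec)
    censoring_hazard_per_year: float = 0.05
    death_fraction: float = 0.3
    rollout_days: int = 150
    effect_window_days: int = 28
    p_dose2: float = 0.8
    dose2_gap_min: int = 21
    dose2_gap_max: int = 84
    p_short_gap: float = 0.0
    p_crossover: float = 0.0
    p_unknown_brand: float = 0.0
    p_missing_age_sex: float = 0.0
    p_short_history: float = 0.05
    extra_history_mean_days: float = 1500.0
    platelet_spec: PlateletSpec = field(default_factory=PlateletSpec)
    seed: int = 0

    def validate(self) -> None:
        def _finite(name: str, value: float) -> None:
            if not math.isfinite(value):
                raise ConfigValidationError(f"{name} must be finite, got {value!r}")

        def _prob(name: str, value: float) -> None:
            _finite(name, value)
            if not 0.0 <= value <= 1.0:
                raise ConfigValidationError(f"{name} must be in [0, 1], got {value!r}")

        def _nonneg(name: str, value: float) -> None:
            _finite(name, value)
            if value < 0:
                raise ConfigValidationError(f"{name} must be non-negative, got {value!r}")

        if self.n_persons <= 0:
            raise ConfigValidationError("n_persons must be positive")
        if self.study_end_day <= self.study_start_day:
            raise ConfigValidationError("study_end_day must exceed study_start_day")
        for brand in (self.target_brand, self.comparator_brand):
            if brand not in self.brand_set:
                raise ConfigValidationError(f"brand {brand!r} not in brand_set")
        for name, params in self.outcome_spec.items():
            _nonneg(f"outcome {name} baseline_rate", params.baseline_rate)
            _finite(f"outcome {name} true_rr", params.true_rr)
            if params.true_rr <= 0:
                raise ConfigValidationError(f"outcome {name} true_rr must be > 0")
            for cov, val in params.covariate_log_hr.items():
                _finite(f"outcome {name} covariate_log_hr[{cov}]", val)
        _nonneg("nc_baseline_rate", self.nc_baseline_rate)
        if self.n_negative_controls < 0:
            raise ConfigValidationError("n_negative_controls must be >= 0")
        for cov, val in self.assignment_coefficients.items():
            _finite(f"assignment_coefficients[{cov}]", val)
        _finite("assignment_intercept", self.assignment_intercept)
        _finite("systematic_error.mean", self.systematic_error.mean)
        _nonneg("systematic_error.sd", self.systematic_error.sd)
        _nonneg("censoring_hazard_per_year", self.censoring_hazard_per_year)
        cov = self.covariate_spec
        _prob("covariate_spec.p_female", cov.p_female)
        for name, p in cov.comorbidity_prevalence.items():
            _prob(f"comorbidity_prevalence[{name}]", p)
        for name, m in cov.utilisation_means.items():
            _nonneg(f"utilisation_means[{name}]", m)
        for name in (
            "p_dose2",
            "p_short_gap",
            "p_crossover",
            "p_unknown_brand",
            "p_missing_age_sex",
            "p_short_history",
            "death_fraction",
        ):
            _prob(name, getattr(self, name))
        ps = self.platelet_spec
        for name in ("p_measured_near_event", "p_low_given_measured", "background_probability"):
            _prob(f"platelet_spec.{name}", getattr(ps, name))
        for name in ("normal_mean", "normal_sd", "low_mean", "low_sd", "floor"):
            _nonneg(f"platelet_spec.{name}", getattr(ps, name))

    def negative_control_names(self) -> list[str]:
        return [f"nc_{i:03d}" for i in range(self.n_negative_controls)]

    def to_yaml(self, path: str) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str) -> "SimulationConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict[str, Any]) -> "SimulationConfig":
        raw = dict(raw)
        if "covariate_spec" in raw and isinstance(raw["covariate_spec"], dict):
            raw["covariate_spec"] = CovariateSpec(**raw["covariate_spec"])
        if "platelet_spec" in raw and isinstance(raw["platelet_spec"], dict):
            raw["platelet_spec"] = PlateletSpec(**raw["platelet_spec"])
        if "systematic_error" in raw and isinstance(raw["systematic_error"], dict):
            raw["systematic_error"] = SystematicErrorSpec(**raw["systematic_error"])
        if "outcome_spec" in raw:
            raw["outcome_spec"] = {
                name: params if isinstance(params, OutcomeParams) else OutcomeParams(**params)
                for name, params in raw["outcome_spec"].items()
            }
        if "brand_set" in raw:
            raw["brand_set"] = tuple(raw["brand_set"])
        cfg = cls(**raw)
        return cfg
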