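"""Simulation experiments exercising the pipeline under known truth.

These drivers define the study conditions used to validate the method:
systematic-error injection with empirical-calibration recovery, propensity
balance under measured confounding, empirical-null parameter recovery, and
end-to-end recovery of a generating rate ratio through the full matched,
calibrated, meta-analysed pipeline. The analysis scripts, the test suite and
the acceptance script all run these same functions.
"""
from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .calibration import calibrate, fit_null
from .cohorts import build_cohort, extract_covariates
from .config import CovariateSpec, OutcomeParams, PlateletSpec, SimulationConfig, SystematicErrorSpec
from .estimation import estimate_cell
from .outcomes import (
    OutcomeDefinition,
    OutcomeRegistry,
    default_registry,
    first_event_day_table,
)
from .pipeline import Comparison, StudyConfig, derive_seed, run_study
from .propensity import (
    compute_smd,
    fit_propensity_model,
    greedy_match,
    matched_persons,
    predict_logit,
)
from .synthetic import generate_database

#: Confounding used across experiments: age, sex and comorbidity drive both
#: brand assignment (log-odds below 1 per covariate) and outcome hazards.
MODERATE_ASSIGNMENT = {
    "age_decade": 0.3,
    "sex_female": 0.2,
    "hypertension": 0.4,
    "diabetes": 0.25,
    "drug_record": 0.05,
}


def _lean_covariates() -> CovariateSpec:
    """Covariate spec without utilisation noise, for estimation-only runs."""
    return CovariateSpec(comorbidity_prevalence={}, utilisation_means={})


def bias_calibration_experiment(
    n_reps: int = 500,
    n_persons: int = 120_000,
    n_negative_controls: int = 50,
    bias_mean: float = 0.1,
    bias_sd: float = 0.05,
    true_rr: float = 2.0,
    outcome_rate: float = 0.045,
    nc_rate_range: tuple[float, float] = (0.02, 0.2),
    seed: int = 0,
) -> dict[str, float]:
    """Injected-bias recovery: does empirical calibration restore coverage?

    Each replicate generates a database with random brand assignment (no
    confounding), a target-arm ascertainment bias drawn per outcome from
    Normal(bias_mean, bias_sd^2) on the log scale, one outcome with a true
    rate ratio, and negative controls whose baseline rates are log-spaced
    over ``nc_rate_range`` — real negative-control sets span a wide
    incidence range, and the precise (common-outcome) controls are what
    make the between-outcome error SD identifiable at all. Crude per-arm
    cells in the 28-day window give the outcome estimate and the NC
    estimates; the empirical null is fitted to the NCs and the outcome
    estimate calibrated.

    Returns coverage of the true RR by the uncalibrated and calibrated 95%
    CIs across replicates, the calibrated false-positive rate on one held-out
    NC, and the average fitted null parameters.
    """
    nc_fit = [f"nc_{i:03d}" for i in range(n_negative_controls)]
    nc_held_out = "nc_held_out"
    nc_rates = np.geomspace(nc_rate_range[0], nc_rate_range[1], n_negative_controls)
    outcome_spec = {"study_outcome": OutcomeParams(outcome_rate, true_rr)}
    for name, rate in zip(nc_fit, nc_rates):
        outcome_spec[name] = OutcomeParams(float(rate), 1.0)
    outcome_spec[nc_held_out] = OutcomeParams(float(np.median(nc_rates)), 1.0)
    base_cfg = SimulationConfig(
        n_persons=n_persons,
        study_end_day=90,
        rollout_days=60,
        covariate_spec=_lean_covariates(),
        outcome_spec=outcome_spec,
        n_negative_controls=0,
        nc_covariate_log_hr={},
        systematic_error=SystematicErrorSpec(bias_mean, bias_sd),
        p_short_history=0.0,
        extra_history_mean_days=60.0,
        platelet_spec=PlateletSpec(background_probability=0.0),
    )
    registry = OutcomeRegistry(
        [OutcomeDefinition("study_outcome", ("study_outcome",))]
        + [
            OutcomeDefinition(nc, (nc,), is_negative_control=True)
            for nc in [*nc_fit, nc_held_out]
        ]
    )

    uncal_cover = cal_cover = 0
    nc_uncal_sig = nc_cal_sig = 0
    mus, sigmas = [], []
    n_done = 0
    for rep in range(n_reps):
        db = generate_database(base_cfg, derive_seed(seed, "bias_calibration", rep))
        cohort_t = build_cohort(db, base_cfg.target_brand, 1, arm="target")
        cohort_c = build_cohort(db, base_cfg.comparator_brand, 1, arm="comparator")

        all_outcomes = ["study_outcome", *nc_fit, nc_held_out]
        days_t = first_event_day_table(db, cohort_t, all_outcomes, registry)
        days_c = first_event_day_table(db, cohort_c, all_outcomes, registry)

        def cell_for(outcome: str):
            return estimate_cell(cohort_t, cohort_c, days_t[outcome], days_c[outcome])

        nc_estimates = [cell_for(nc).effect for nc in nc_fit]
        usable = [(e.log_rr, e.se) for e in nc_estimates if e.estimable]
        if len(usable) < 5:
            continue
        null = fit_null(usable)
        mus.append(null.mu)
        sigmas.append(null.sigma)

        outcome_est = cell_for("study_outcome").effect
        if not outcome_est.estimable:
            continue
        n_done += 1
        uncal_cover += outcome_est.ci95_low <= true_rr <= outcome_est.ci95_high
        cal = calibrate(outcome_est, null)
        cal_cover += cal.ci95_low <= true_rr <= cal.ci95_high

        held = cell_for(nc_held_out).effect
        if held.estimable:
            nc_uncal_sig += held.p_value < 0.05
            nc_cal_sig += calibrate(held, null).p_value < 0.05

    return {
        "n_reps": n_done,
        "uncalibrated_coverage": uncal_cover / n_done,
        "calibrated_coverage": cal_cover / n_done,
        "nc_uncalibrated_type1": nc_uncal_sig / n_done,
        "nc_calibrated_type1": nc_cal_sig / n_done,
        "mean_null_mu": float(np.mean(mus)),
        "mean_null_sigma": float(np.mean(sigmas)),
    }


def null_recovery_experiment(
    m: int = 100,
    mu: float = 0.2,
    sigma: float = 0.1,
    tau_low: float = 0.05,
    tau_high: float = 0.25,
    seed: int = 0,
) -> dict[str, float]:
    """Empirical-null maximum-likelihood recovery from simulated NC pairs.

    Draws m negative-control estimates theta_i = mu + N(0, sigma^2) +
    N(0, tau_i^2) with tau_i uniform on [tau_low, tau_high], fits the null,
    and reports estimates with their asymptotic standard errors.
    """
    rng = np.random.default_rng(seed)
    tau = rng.uniform(tau_low, tau_high, m)
    theta = mu + rng.normal(0.0, sigma, m) + rng.normal(0.0, tau)
    null = fit_null(list(zip(theta, tau)))
    # asymptotic SEs from the average Fisher information of the marginal model
    var_i = sigma**2 + tau**2
    se_mu = float(np.sqrt(1.0 / np.sum(1.0 / var_i)))
    se_sigma = float(np.sqrt(1.0 / np.sum(2.0 * sigma**2 / var_i**2))) if sigma > 0 else np.nan
    return {
        "mu_hat": null.mu,
        "sigma_hat": null.sigma,
        "mu_true": mu,
        "sigma_true": sigma,
        "se_mu": se_mu,
        "se_sigma": se_sigma,
        "m": m,
    }


def balance_experiment(
    n_seeds: int = 50,
    n_persons: int = 40_000,
    smd_threshold: float = 0.1,
    seed: int = 0,
) -> dict[str, float]:
    """Fraction of seeds achieving post-match balance under moderate measured
    confounding with ~20 000 persons per arm.

    Also checks the monotonicity property that matching does not worsen the
    covariate-averaged |SMD|.
    """
    cfg = SimulationConfig(
        n_persons=n_persons,
        n_negative_controls=0,
        assignment_intercept=-0.5,
        assignment_coefficients=dict(MODERATE_ASSIGNMENT),
    )
    passed = 0
    improved = 0
    max_smds = []
    for s in range(n_seeds):
        db = generate_database(cfg, derive_seed(seed, "balance", s))
        ct = build_cohort(db, cfg.target_brand, 1, arm="target")
        cc = build_cohort(db, cfg.comparator_brand, 1, arm="comparator")
        combined = pd.concat([ct, cc], ignore_index=True)
        covs = extract_covariates(db, combined)
        model = fit_propensity_model(covs, (combined["arm"] == "target").to_numpy(), lambda_grid=[1.0])
        logits = pd.Series(predict_logit(model, covs), index=covs.person_ids)
        sets = greedy_match(logits.loc[ct["person_id"]], logits.loc[cc["person_id"]], seed=s)
        b_ids, c_ids = matched_persons(sets)
        m_t, m_c = (c_ids, b_ids) if sets[0].reverse else (b_ids, c_ids)
        pre = compute_smd(covs, ct["person_id"].to_numpy(), cc["person_id"].to_numpy())
        post = compute_smd(covs, m_t, m_c)
        max_smds.append(post.max_abs_post)
        passed += post.max_abs_post < smd_threshold
        improved += (
            post.table["smd_post"].abs().mean() <= pre.table["smd_post"].abs().mean()
        )
    return {
        "n_seeds": n_seeds,
        "fraction_balanced": passed / n_seeds,
        "fraction_improved": improved / n_seeds,
        "median_max_smd": float(np.median(max_smds)),
    }


def end_to_end_recovery(
    n_reps: int = 60,
    n_persons: int = 40_000,
    n_databases: int = 2,
    n_negative_controls: int = 15,
    true_rr: float = 1.33,
    outcome_rate: float = 5e-3,
    seed: int = 0,
    rematch_per_outcome: bool = False,
) -> dict[str, float]:
    """Full-pipeline recovery of a generating rate ratio.

    Each replicate simulates ``n_databases`` confounded two-arm databases
    with one outcome at ``true_rr`` (events per person-year baseline rate
    ``outcome_rate``), runs the complete study (cohorts, propensity matching,
    diagnostics, estimation, per-database and pooled calibration,
    random-effects pooling), and checks whether the pooled calibrated 95% CI
    contains the truth.
    """
    registry = default_registry([f"nc_{i:03d}" for i in range(n_negative_controls)])
    outcome_spec = {
        "thrombocytopenia": OutcomeParams(outcome_rate, true_rr, {"age_decade": 0.3})
    }
    cover = 0
    n_done = 0
    log_rrs = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for rep in range(n_reps):
            dbs = {}
            for d in range(n_databases):
                cfg = SimulationConfig(
                    n_persons=n_persons,
                    n_negative_controls=n_negative_controls,
                    nc_baseline_rate=0.05,
                    assignment_intercept=-0.3,
                    assignment_coefficients=dict(MODERATE_ASSIGNMENT),
                    outcome_spec=outcome_spec,
                )
                dbs[f"db_{d}"] = generate_database(cfg, derive_seed(seed, "e2e", rep, d))
            study = StudyConfig(
                comparisons=[Comparison("adeno_vs_mrna_d1", "ChAdOx1-S", 1, "BNT162b2", 1)],
                outcomes=["thrombocytopenia"],
                lambda_grid=[1.0],
                master_seed=derive_seed(seed, "e2e_study", rep),
                rematch_per_outcome=rematch_per_outcome,
            )
            result = run_study(study, dbs, registry=registry)
            if result.meta_estimates.empty:
                continue
            row = result.meta_estimates.iloc[0]
            if not np.isfinite(row["calibrated_rr"]):
                continue
            n_done += 1
            log_rrs.append(np.log(row["calibrated_rr"]))
            cover += row["calibrated_ci95_low"] <= true_rr <= row["calibrated_ci95_high"]
    return {
        "n_reps": n_done,
        "coverage": cover / n_done,
        "geometric_mean_rr": float(np.exp(np.mean(log_rrs))),
        "true_rr": true_rr,
    }
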