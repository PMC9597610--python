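"""End-to-end study orchestration.

For every (database, comparison) pair the driver builds the two vaccination
cohorts, fits the propensity model, matches, and applies the three study
diagnostics with their asymmetric consequences:

* covariate-balance failure (any post-match |SMD| >= 0.1) kills the whole
  database-specific analysis AND excludes the database from meta-analysis;
* a power failure (MDRR > 5) suppresses the database-specific estimate but
  the cell still contributes to meta-analysis;
* a negative-control failure (>= 20% of NC CIs excluding 1) demotes the
  database's results to calibrated-only.

Database-specific estimates are calibrated against the database's own
empirical null; pooled estimates are calibrated against pooled negative
controls. Everything is deterministic under the master seed, with one seed
per (database, comparison, stage) derived by stable hashing so adding a
comparison does not perturb existing results.
"""
from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import __version__ as _pkg_version
from .calibration import CalibratedEstimate, NullDistribution, calibrate, fit_null, nc_diagnostic
from .cohorts import (
    CovariateExtractionSpec,
    EligibilityRules,
    build_cohort,
    extract_covariates,
    subsample_cohort,
)
from .errors import CalibrationError, MetaAnalysisError, VaxSafetyError
from .estimation import (
    CellEstimate,
    absolute_risk_difference,
    estimate_cell,
    rate_difference,
    stratified_estimates,
)
from .meta import dl_meta, inclusion_rule, pooled_calibration
from .outcomes import (
    OutcomeRegistry,
    TTSDefinition,
    default_registry,
    exclude_prior_history,
    first_event_days,
    tts_event_days,
)
from .propensity import (
    balance_gate,
    compute_smd,
    fit_propensity_model,
    greedy_match,
    matched_persons,
    matches_frame,
    predict_logit,
)
from .synthetic import SyntheticDatabase, read_database


def derive_seed(master: int, *parts: object) -> int:
    """Stable sub-seed below 2^31 from a master seed and context labels."""
    key = "|".join([str(master), *(str(p) for p in parts)])
    digest = hashlib.blake2s(key.encode()).digest()
    return int.from_bytes(digest[:4], "little") % (2**31)


@dataclass
class Comparison:
    name: str
    target_brand: str
    target_dose: int
    comparator_brand: str
    comparator_dose: int


@dataclass
class StudyConfig:
    """Thresholds, comparison list and analysis options for one study run."""

    comparisons: list[Comparison]
    outcomes: list[str]
    tts_definitions: list[TTSDefinition] = field(default_factory=list)
    eligibility: EligibilityRules = field(default_factory=EligibilityRules)
    covariate_spec: CovariateExtractionSpec = field(default_factory=CovariateExtractionSpec)
    risk_window_days: int = 28
    smd_threshold: float = 0.1
    mdrr_threshold: float = 5.0
    nc_fraction_threshold: float = 0.20
    alpha: float = 0.05
    power: float = 0.80
    caliper_sd: float = 0.2
    max_ratio: int = 4
    lambda_grid: list[float] | None = None
    cv_folds: int = 10
    min_negative_controls: int = 5
    subsample: dict[str, float] = field(default_factory=dict)
    stratify: bool = False
    rematch_per_outcome: bool = True
    master_seed: int = 0


@dataclass
class StudyResult:
    estimates: pd.DataFrame
    meta_estimates: pd.DataFrame
    diagnostics: pd.DataFrame
    balance: pd.DataFrame
    negative_controls: pd.DataFrame
    matches: pd.DataFrame
    forest: pd.DataFrame
    strata: pd.DataFrame
    log: list[str]
    manifest: dict

    def write(self, out_dir: str) -> None:
        os.makedirs(out_dir, exist_ok=True)
        for name in (
            "estimates",
            "meta_estimates",
            "diagnostics",
            "balance",
            "negative_controls",
            "matches",
            "forest",
            "strata",
        ):
            getattr(self, name).to_csv(os.path.join(out_dir, f"{name}.csv"), index=False)
        with open(os.path.join(out_dir, "run.log"), "w", encoding="utf-8") as fh:
            fh.write("\n".join(self.log) + "\n")
        with open(os.path.join(out_dir, "manifest.json"), "w", encoding="utf-8") as fh:
            json.dump(self.manifest, fh, indent=2, default=str)


def _cell_row(base: dict, cell: CellEstimate | None, status: str, calibrated: CalibratedEstimate | None, calibrated_only: bool) -> dict:
    row = dict(base)
    row["status"] = status
    row["calibrated_only"] = calibrated_only
    if cell is not None:
        eff = cell.effect
        row.update(
            events_target=eff.events_target,
            py_target=round(eff.py_target, 6),
            events_comparator=eff.events_comparator,
            py_comparator=round(eff.py_comparator, 6),
            rate_target=cell.rate_target.rate_per_1000py,
            rate_target_low=cell.rate_target.ci95_low,
            rate_target_high=cell.rate_target.ci95_high,
            rate_comparator=cell.rate_comparator.rate_per_1000py,
            rate_comparator_low=cell.rate_comparator.ci95_low,
            rate_comparator_high=cell.rate_comparator.ci95_high,
            mdrr=cell.power.mdrr,
            mdrr_pass=cell.power.passed,
        )
        reportable = status == "reported"
        row.update(
            rr=eff.rr if reportable else np.nan,
            ci95_low=eff.ci95_low if reportable else np.nan,
            ci95_high=eff.ci95_high if reportable else np.nan,
            p_value=eff.p_value if reportable else np.nan,
        )
        if reportable and eff.estimable:
            ird, ird_lo, ird_hi = rate_difference(cell.rate_target, cell.rate_comparator)
            ard, ard_lo, ard_hi = absolute_risk_difference(cell.rate_target, cell.rate_comparator)
            row.update(ird=ird, ird_low=ird_lo, ird_high=ird_hi, ard=ard, ard_low=ard_lo, ard_high=ard_hi)
        if calibrated is not None and reportable:
            row.update(
                calibrated_rr=calibrated.rr,
                calibrated_ci95_low=calibrated.ci95_low,
                calibrated_ci95_high=calibrated.ci95_high,
                calibrated_p=calibrated.p_value,
            )
    return row


def run_study(
    config: StudyConfig,
    databases: dict[str, SyntheticDatabase | str],
    registry: OutcomeRegistry | None = None,
) -> StudyResult:
    """Run the full study over named databases (objects or directory paths)."""
    dbs: dict[str, SyntheticDatabase] = {
        name: db if isinstance(db, SyntheticDatabase) else read_database(db)
        for name, db in databases.items()
    }
    if registry is None:
        nc_names: list[str] = []
        for db in dbs.values():
            if db.ground_truth is not None:
                gt = db.ground_truth.outcomes
                nc_names = list(gt.loc[gt["is_negative_control"], "outcome"])
                break
        registry = default_registry(nc_names)
    nc_outcomes = registry.negative_controls()
    tts_by_name = {t.name: t for t in config.tts_definitions}
    analysis_outcomes = list(config.outcomes) + list(tts_by_name)

    log: list[str] = []
    est_rows: list[dict] = []
    nc_rows: list[dict] = []
    balance_rows: list[dict] = []
    diag_rows: list[dict] = []
    match_rows: list[pd.DataFrame] = []
    strata_rows: list[dict] = []

    # in-memory estimates retained for meta-analysis
    effects: dict[tuple[str, str, str], CellEstimate] = {}  # (comparison, db, outcome)
    nc_effects: dict[tuple[str, str], dict[str, object]] = {}  # (comparison, db) -> {nc: EffectEstimate}
    balance_pass: dict[tuple[str, str], bool] = {}

    for comp in config.comparisons:
        for db_name, db in dbs.items():
            ctx = f"{db_name}/{comp.name}"
            try:
                result = _analyse_database(
                    config, comp, db_name, db, registry, nc_outcomes, tts_by_name,
                    analysis_outcomes, log,
                )
            except VaxSafetyError as exc:
                log.append(f"[{ctx}] quarantined: {type(exc).__name__}: {exc}")
                diag_rows.append(
                    {"comparison": comp.name, "database": db_name, "stage": "error", "detail": str(exc)}
                )
                continue
            est_rows.extend(result["est_rows"])
            nc_rows.extend(result["nc_rows"])
            balance_rows.extend(result["balance_rows"])
            diag_rows.extend(result["diag_rows"])
            strata_rows.extend(result["strata_rows"])
            if result["matches"] is not None:
                match_rows.append(result["matches"])
            effects.update(result["effects"])
            if result["nc_effects"] is not None:
                nc_effects[(comp.name, db_name)] = result["nc_effects"]
            balance_pass[(comp.name, db_name)] = result["balance_pass"]

    # --- meta-analysis ------------------------------------------------------
    meta_rows: list[dict] = []
    for comp in config.comparisons:
        included = inclusion_rule(
            {db: {"balance": balance_pass.get((comp.name, db), False)} for db in dbs}
        )
        log.append(f"[meta/{comp.name}] contributing databases: {included or 'none'}")
        for outcome in analysis_outcomes:
            inputs = []
            for db_name in included:
                cell = effects.get((comp.name, db_name, outcome))
                if cell is not None and cell.effect.estimable:
                    inputs.append((cell.effect.log_rr, cell.effect.se))
            if not inputs:
                continue
            try:
                pooled = dl_meta(inputs)
            except MetaAnalysisError:
                continue
            nc_by_db = {
                db_name: nc_effects[(comp.name, db_name)]
                for db_name in included
                if (comp.name, db_name) in nc_effects
            }
            calibrated, pooled_null = pooled_calibration(
                nc_by_db, pooled, min_controls=config.min_negative_controls
            )
            meta_rows.append(
                {
                    "comparison": comp.name,
                    "outcome": outcome,
                    "k": pooled.k,
                    "databases": ";".join(
                        db for db in included if (comp.name, db, outcome) in effects
                    ),
                    "rr": pooled.rr,
                    "ci95_low": pooled.ci95_low,
                    "ci95_high": pooled.ci95_high,
                    "p_value": pooled.p_value,
                    "q": pooled.q,
                    "tau2": pooled.tau2,
                    "i2": pooled.i2,
                    "heterogeneity_warning": pooled.heterogeneity_warning,
                    "calibrated_rr": calibrated.rr if calibrated else np.nan,
                    "calibrated_ci95_low": calibrated.ci95_low if calibrated else np.nan,
                    "calibrated_ci95_high": calibrated.ci95_high if calibrated else np.nan,
                    "calibrated_p": calibrated.p_value if calibrated else np.nan,
                    "pooled_null_mu": pooled_null.mu if pooled_null else np.nan,
                    "pooled_null_sigma": pooled_null.sigma if pooled_null else np.nan,
                }
            )

    estimates = pd.DataFrame(est_rows)
    meta_estimates = pd.DataFrame(meta_rows)
    forest = report_forest(meta_estimates, estimates)
    manifest = {
        "package_version": _pkg_version,
        "master_seed": config.master_seed,
        "databases": list(dbs),
        "config": asdict(config),
    }
    return StudyResult(
        estimates=estimates,
        meta_estimates=meta_estimates,
        diagnostics=pd.DataFrame(diag_rows),
        balance=pd.DataFrame(balance_rows),
        negative_controls=pd.DataFrame(nc_rows),
        matches=pd.concat(match_rows, ignore_index=True) if match_rows else pd.DataFrame(columns=["comparison", "database", "set_id", "role", "person_id"]),
        forest=forest,
        strata=pd.DataFrame(strata_rows),
        log=log,
        manifest=manifest,
    )


def _analyse_database(
    config: StudyConfig,
    comp: Comparison,
    db_name: str,
    db: SyntheticDatabase,
    registry: OutcomeRegistry,
    nc_outcomes: list[str],
    tts_by_name: dict[str, TTSDefinition],
    analysis_outcomes: list[str],
    log: list[str],
) -> dict:
    seed = config.master_seed
    ctx = f"{db_name}/{comp.name}"
    base = {"comparison": comp.name, "database": db_name}
    out = {
        "est_rows": [], "nc_rows": [], "balance_rows": [], "diag_rows": [],
        "strata_rows": [], "matches": None, "effects": {}, "nc_effects": None,
        "balance_pass": False,
    }

    cohort_t = build_cohort(db, comp.target_brand, comp.target_dose, config.eligibility, config.risk_window_days, arm="target")
    cohort_c = build_cohort(db, comp.comparator_brand, comp.comparator_dose, config.eligibility, config.risk_window_days, arm="comparator")
    frac = config.subsample.get(db_name, 1.0)
    if frac < 1.0:
        cohort_t = subsample_cohort(cohort_t, frac, derive_seed(seed, db_name, comp.name, "subsample_t"))
        cohort_c = subsample_cohort(cohort_c, frac, derive_seed(seed, db_name, comp.name, "subsample_c"))
    log.append(f"[{ctx}] cohorts: target n={len(cohort_t)}, comparator n={len(cohort_c)}")
    if cohort_t.empty or cohort_c.empty:
        out["diag_rows"].append({**base, "stage": "cohort", "detail": "empty arm", "passed": False})
        for outcome in analysis_outcomes:
            out["est_rows"].append({**base, "outcome": outcome, "status": "empty_cohort", "calibrated_only": False})
        return out

    combined = pd.concat([cohort_t, cohort_c], ignore_index=True)
    covs = extract_covariates(db, combined, config.covariate_spec)
    arm = (combined["arm"] == "target").to_numpy()
    ps = fit_propensity_model(
        covs, arm, config.lambda_grid, folds=config.cv_folds,
        seed=derive_seed(seed, db_name, comp.name, "ps"),
    )
    logits = pd.Series(predict_logit(ps, covs), index=covs.person_ids)
    logit_t = logits.loc[cohort_t["person_id"]]
    logit_c = logits.loc[cohort_c["person_id"]]

    sets = greedy_match(
        logit_t, logit_c, config.caliper_sd, config.max_ratio,
        seed=derive_seed(seed, db_name, comp.name, "match"),
    )
    base_ids, cand_ids = matched_persons(sets)
    reverse = bool(sets and sets[0].reverse)
    m_t, m_c = (cand_ids, base_ids) if reverse else (base_ids, cand_ids)
    mdf = matches_frame(sets)
    mdf.insert(0, "database", db_name)
    mdf.insert(0, "comparison", comp.name)
    out["matches"] = mdf

    pre = compute_smd(covs, cohort_t["person_id"].to_numpy(), cohort_c["person_id"].to_numpy())
    balance = compute_smd(covs, m_t, m_c, pre=pre.table.rename(columns={"smd_post": "smd_post"}))
    bt = balance.table.copy()
    bt.insert(0, "database", db_name)
    bt.insert(0, "comparison", comp.name)
    out["balance_rows"] = bt.to_dict("records")
    passed, offenders = balance_gate(balance, config.smd_threshold)
    out["balance_pass"] = passed
    out["diag_rows"].append(
        {**base, "stage": "balance", "passed": passed, "detail": f"max |SMD|={balance.max_abs_post:.4f}" + (f"; offenders: {offenders[:5]}" if offenders else "")}
    )
    log.append(f"[{ctx}] balance gate {'PASS' if passed else 'FAIL'} (max |SMD| {balance.max_abs_post:.4f})")
    if not passed:
        for outcome in analysis_outcomes:
            out["est_rows"].append({**base, "outcome": outcome, "status": "skipped_balance", "calibrated_only": False})
        return out

    matched_t = cohort_t[cohort_t["person_id"].isin(m_t)]
    matched_c = cohort_c[cohort_c["person_id"].isin(m_c)]

    def _matched_for(outcome_name: str, history_outcome: str) -> tuple[pd.DataFrame, pd.DataFrame]:
        """Per-outcome prior-history exclusion, then (re)matching."""
        if config.rematch_per_outcome:
            ct = exclude_prior_history(cohort_t, db, history_outcome, registry)
            cc = exclude_prior_history(cohort_c, db, history_outcome, registry)
            if ct.empty or cc.empty:
                return ct.iloc[:0], cc.iloc[:0]
            s = greedy_match(
                logit_t.loc[ct["person_id"]], logit_c.loc[cc["person_id"]],
                config.caliper_sd, config.max_ratio,
                seed=derive_seed(seed, db_name, comp.name, "match", outcome_name),
            )
            b_ids, c_ids = matched_persons(s)
            rev = bool(s and s[0].reverse)
            mt, mc = (c_ids, b_ids) if rev else (b_ids, c_ids)
            return ct[ct["person_id"].isin(mt)], cc[cc["person_id"].isin(mc)]
        ct = exclude_prior_history(matched_t, db, history_outcome, registry)
        cc = exclude_prior_history(matched_c, db, history_outcome, registry)
        return ct, cc

    def _event_days(cohort: pd.DataFrame, outcome_name: str) -> pd.Series:
        if outcome_name in tts_by_name:
            return tts_event_days(db, cohort, tts_by_name[outcome_name], registry)
        return first_event_days(db, cohort, outcome_name, registry)

    # negative controls first: their estimates drive the bias diagnostic and null
    nc_ests: dict[str, object] = {}
    for nc in nc_outcomes:
        ct, cc = _matched_for(nc, nc)
        if ct.empty or cc.empty:
            continue
        cell = estimate_cell(ct, cc, _event_days(ct, nc), _event_days(cc, nc),
                             config.alpha, config.power, config.mdrr_threshold)
        nc_ests[nc] = cell.effect
    fraction, nc_pass, n_estimable = nc_diagnostic(list(nc_ests.values()), config.nc_fraction_threshold)
    calibrated_only = not nc_pass
    out["nc_effects"] = nc_ests
    out["diag_rows"].append(
        {**base, "stage": "negative_controls", "passed": nc_pass,
         "detail": f"fraction significant={fraction:.3f} over {n_estimable} estimable NCs"}
    )
    log.append(f"[{ctx}] NC gate {'PASS' if nc_pass else 'FAIL'} ({fraction:.1%} of {n_estimable} NCs significant)")

    null: NullDistribution | None = None
    try:
        null = fit_null(
            [(e.log_rr, e.se) for e in nc_ests.values() if e.estimable],
            min_controls=config.min_negative_controls,
        )
        log.append(f"[{ctx}] empirical null: mu={null.mu:.4f}, sigma={null.sigma:.4f}, m={null.n_controls}")
    except CalibrationError as exc:
        log.append(f"[{ctx}] calibration unavailable: {exc}")
        out["diag_rows"].append({**base, "stage": "calibration", "passed": False, "detail": str(exc)})

    for nc, eff in nc_ests.items():
        out["nc_rows"].append(
            {
                **base, "outcome": nc, "log_rr": eff.log_rr, "se": eff.se,
                "rr": eff.rr, "ci95_low": eff.ci95_low, "ci95_high": eff.ci95_high,
                "estimable": eff.estimable,
                "significant": bool(eff.estimable and (eff.ci95_low > 1 or eff.ci95_high < 1)),
            }
        )

    # study outcomes
    for outcome in analysis_outcomes:
        history_outcome = tts_by_name[outcome].thrombo_outcome if outcome in tts_by_name else outcome
        ct, cc = _matched_for(outcome, history_outcome)
        row_base = {**base, "outcome": outcome, "n_target": len(ct), "n_comparator": len(cc)}
        if ct.empty or cc.empty:
            out["est_rows"].append({**row_base, "status": "empty_cohort", "calibrated_only": calibrated_only})
            continue
        cell = estimate_cell(ct, cc, _event_days(ct, outcome), _event_days(cc, outcome),
                             config.alpha, config.power, config.mdrr_threshold)
        out["effects"][(comp.name, db_name, outcome)] = cell
        if not cell.effect.estimable:
            status = "not_estimable"
        elif not cell.power.passed:
            status = "suppressed_power"
        else:
            status = "reported"
        cal = calibrate(cell.effect, null) if (null is not None and cell.effect.estimable) else None
        out["est_rows"].append(_cell_row(row_base, cell, status, cal, calibrated_only))
        log.append(f"[{ctx}] {outcome}: status={status}, events {cell.effect.events_target}/{cell.effect.events_comparator}, MDRR={cell.power.mdrr:.2f}")

        if config.stratify and status == "reported":
            frame = covs.to_frame()
            age = frame["age"]
            sex = frame["sex_female"].map({1.0: "female", 0.0: "male"})
            srows = stratified_estimates(
                ct, cc, _event_days(ct, outcome), _event_days(cc, outcome),
                age.loc[ct["person_id"]].reset_index(drop=True),
                age.loc[cc["person_id"]].reset_index(drop=True),
                sex.loc[ct["person_id"]].reset_index(drop=True),
                sex.loc[cc["person_id"]].reset_index(drop=True),
                mdrr_threshold=config.mdrr_threshold,
            )
            srows.insert(0, "outcome", outcome)
            srows.insert(0, "database", db_name)
            srows.insert(0, "comparison", comp.name)
            out["strata_rows"].extend(srows.to_dict("records"))
    return out


def report_forest(meta_estimates: pd.DataFrame, estimates: pd.DataFrame) -> pd.DataFrame:
    """Tabular forest: per outcome the database-specific rows (alphabetical)
    then the pooled row (only when two or more databases contributed)."""
    columns = [
        "comparison", "outcome", "source", "rr", "ci95_low", "ci95_high",
        "calibrated_rr", "calibrated_ci95_low", "calibrated_ci95_high",
    ]
    rows: list[dict] = []
    if estimates.empty:
        return pd.DataFrame(columns=columns)
    reported = estimates[estimates["status"] == "reported"] if "status" in estimates else estimates.iloc[:0]
    for (comp, outcome), group in sorted(
        reported.groupby(["comparison", "outcome"]), key=lambda kv: kv[0]
    ):
        for _, r in group.sort_values("database").iterrows():
            rows.append(
                {
                    "comparison": comp, "outcome": outcome, "source": r["database"],
                    "rr": r.get("rr"), "ci95_low": r.get("ci95_low"), "ci95_high": r.get("ci95_high"),
                    "calibrated_rr": r.get("calibrated_rr"), "calibrated_ci95_low": r.get("calibrated_ci95_low"),
                    "calibrated_ci95_high": r.get("calibrated_ci95_high"),
                }
            )
        if not meta_estimates.empty:
            pooled = meta_estimates[
                (meta_estimates["comparison"] == comp)
                & (meta_estimates["outcome"] == outcome)
                & (meta_estimates["k"] >= 2)
            ]
            for _, r in pooled.iterrows():
                rows.append(
                    {
                        "comparison": comp, "outcome": outcome, "source": "pooled",
                        "rr": r["rr"], "ci95_low": r["ci95_low"], "ci95_high": r["ci95_high"],
                        "calibrated_rr": r["calibrated_rr"], "calibrated_ci95_low": r["calibrated_ci95_low"],
                        "calibrated_ci95_high": r["calibrated_ci95_high"],
                    }
                )
    return pd.DataFrame(rows, columns=columns)
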