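"""Generate the two synthetic vaccination databases used by the study run.

Each database holds two-arm first/second-dose vaccination records where age,
sex, comorbidity and healthcare-utilisation covariates drive both brand
assignment and outcome hazards (measured confounding), thromboembolic
outcomes at a few events per 1000 person-years, 40 negative-control outcomes,
and platelet measurements around thrombosis events. Writes
data/db_{a,b}/*.csv and prints arm sizes and ground truth.

Usage: python analysis/01_simulate_databases.py [--seed 1] [--out data]
"""
import argparse
import os

from vaxsafety.config import OutcomeParams, SimulationConfig
from vaxsafety.experiments import MODERATE_ASSIGNMENT
from vaxsafety.pipeline import derive_seed
from vaxsafety.synthetic import generate_database, write_database

OUTCOME_SPEC = {
    "deep_vein_thrombosis": OutcomeParams(1.5e-3, 1.0, {"age_decade": 0.35}, emit_platelets=True),
    "pulmonary_embolism": OutcomeParams(1.9e-3, 1.0, {"age_decade": 0.35}, emit_platelets=True),
    "ischaemic_stroke": OutcomeParams(0.7e-3, 1.0, {"age_decade": 0.35}, emit_platelets=True),
    "myocardial_infarction": OutcomeParams(2.0e-3, 1.0, {"age_decade": 0.35}, emit_platelets=True),
    # the one outcome with a genuine adverse effect of the target vaccine
    "thrombocytopenia": OutcomeParams(5.0e-3, 1.33, {"age_decade": 0.35}),
}


def build_config(n_persons: int = 60_000) -> SimulationConfig:
    return SimulationConfig(
        n_persons=n_persons,
        n_negative_controls=40,
        nc_baseline_rate=0.08,
        assignment_intercept=-0.5,
        assignment_coefficients=dict(MODERATE_ASSIGNMENT),
        outcome_spec=dict(OUTCOME_SPEC),
        p_short_history=0.05,
        p_unknown_brand=0.01,
        p_missing_age_sex=0.01,
        p_short_gap=0.005,
    )


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--out", default="data")
    parser.add_argument("--n-persons", type=int, default=60_000)
    args = parser.parse_args()

    for name in ("db_a", "db_b"):
        cfg = build_config(args.n_persons)
        db = generate_database(cfg, derive_seed(args.seed, "simulate", name))
        out_dir = os.path.join(args.out, name)
        write_database(db, out_dir)
        cfg.to_yaml(os.path.join(out_dir, "sim_config.yaml"))
        d1 = db.vaccinations[db.vaccinations["dose_number"] == 1]
        arms = d1["brand"].value_counts()
        print(f"{name}: {len(db.persons)} persons, {len(db.events)} events -> {out_dir}")
        print(f"  dose-1 arms: {arms.to_dict()}")
        truth = db.ground_truth.outcomes
        flagged = truth[truth["true_rr"] != 1.0]
        print(f"  outcomes with true RR != 1: {flagged[['outcome', 'true_rr']].to_dict('records')}")


if __name__ == "__main__":
    main()
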