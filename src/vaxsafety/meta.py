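"""DerSimonian-Laird random-effects meta-analysis across databases.

Per-database log rate ratios are pooled with inverse-variance weights
inflated by the method-of-moments between-database variance tau^2;
heterogeneity is summarised by Cochran's Q and I^2. Pooled estimates are
empirically calibrated against pooled negative-control estimates (each NC is
itself meta-analysed across databases first).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .calibration import CalibratedEstimate, NullDistribution, calibrate, fit_null
from .errors import CalibrationError, MetaAnalysisError
from .estimation import Z975, EffectEstimate


@dataclass
class MetaEstimate:
    log_rr: float
    se: float
    rr: float
    ci95_low: float
    ci95_high: float
    p_value: float
    q: float
    tau2: float
    i2: float
    k: int
    heterogeneity_warning: bool = False

    def as_effect(self) -> EffectEstimate:
        """View as an EffectEstimate so calibration applies unchanged."""
        return EffectEstimate(
            self.log_rr, self.se, self.rr, self.ci95_low, self.ci95_high,
            self.p_value, -1, np.nan, -1, np.nan, True,
        )


def dl_meta(estimates: list[tuple[float, float]], i2_warn: float = 60.0) -> MetaEstimate:
    """DerSimonian-Laird pooling of (theta_i, tau_i) inputs.

    With k=1 the pooled estimate is the input with tau^2 = 0 and I^2 reported
    as 0. A heterogeneity warning is set (and warned) at I^2 above
    ``i2_warn`` percent; it does not suppress the estimate.
    """
    pairs = [(t, s) for t, s in estimates if np.isfinite(t) and np.isfinite(s) and s > 0]
    k = len(pairs)
    if k == 0:
        raise MetaAnalysisError("meta-analysis requires at least one estimable input")
    theta = np.array([p[0] for p in pairs])
    tau = np.array([p[1] for p in pairs])
    w = 1.0 / tau**2
    theta_fe = float(np.sum(w * theta) / np.sum(w))
    q = float(np.sum(w * (theta - theta_fe) ** 2))
    if k > 1:
        denom = np.sum(w) - np.sum(w**2) / np.sum(w)
        tau2 = max(0.0, (q - (k - 1)) / denom) if denom > 0 else 0.0
        i2 = max(0.0, (q - (k - 1)) / q) * 100.0 if q > 0 else 0.0
    else:
        tau2 = 0.0
        i2 = 0.0
    w_star = 1.0 / (tau**2 + tau2)
    pooled = float(np.sum(w_star * theta) / np.sum(w_star))
    se = float(1.0 / np.sqrt(np.sum(w_star)))
    p = float(2 * stats.norm.sf(abs(pooled) / se))
    warn = i2 > i2_warn
    if warn:
        warnings.warn(
            f"high between-database heterogeneity (I^2 = {i2:.0f}%): pooled estimate unreliable",
            stacklevel=2,
        )
    return MetaEstimate(
        pooled, se, float(np.exp(pooled)),
        float(np.exp(pooled - Z975 * se)), float(np.exp(pooled + Z975 * se)),
        p, q, tau2, i2, k, warn,
    )


def pooled_calibration(
    nc_estimates_by_db: dict[str, dict[str, EffectEstimate]],
    outcome_meta: MetaEstimate,
    min_controls: int = 5,
) -> tuple[CalibratedEstimate | None, NullDistribution | None]:
    """Calibrate a pooled outcome estimate with pooled negative controls.

    Each negative control is meta-analysed across databases, the empirical
    null is fitted to those pooled NC estimates, and the pooled outcome
    estimate is calibrated against it. Returns (calibrated or None, null or
    None); None means too few pooled NCs, in which case the uncalibrated
    pooled estimate is still reportable upstream.
    """
    by_nc: dict[str, list[tuple[float, float]]] = {}
    for db_estimates in nc_estimates_by_db.values():
        for nc, est in db_estimates.items():
            if est.estimable:
                by_nc.setdefault(nc, []).append((est.log_rr, est.se))
    pooled_ncs = [dl_meta(v) for v in by_nc.values() if v]
    try:
        null = fit_null([(m.log_rr, m.se) for m in pooled_ncs], min_controls=min_controls)
    except CalibrationError:
        return None, None
    calibrated = calibrate(outcome_meta.as_effect(), null)
    return calibrated, null


def pool_calibrated_estimates(calibrated_by_db: list[CalibratedEstimate]) -> MetaEstimate:
    """Alternative pooling route: meta-analyse the per-database *calibrated*
    estimates (bias-shifted, variance-widened) instead of calibrating the
    pooled estimate against a pooled null."""
    inputs = []
    for cal in calibrated_by_db:
        if np.isfinite(cal.rr):
            se = float(np.sqrt(cal.null.sigma**2 + cal.uncalibrated.se**2))
            inputs.append((float(np.log(cal.rr)), se))
    return dl_meta(inputs)


def inclusion_rule(diagnostics: dict[str, dict[str, bool]]) -> list[str]:
    """Databases contributing to the meta-analysis of one comparison.

    Inclusion requires only the covariate-balance diagnostic; the power and
    negative-control gates suppress database-specific reporting but do not
    exclude a database from pooling.
    """
    return [db for db, gates in diagnostics.items() if gates.get("balance", False)]
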