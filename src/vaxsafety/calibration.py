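"""Negative-control empirical calibration.

Negative-control outcomes are assumed causally unrelated to vaccination, so
their estimated log rate ratios measure residual systematic error. The
empirical null models that error as Normal(mu, sigma^2) on the log-RR scale:
each observed NC estimate theta_i with sampling SE tau_i is treated as a draw
from Normal(mu, sigma^2 + tau_i^2), and (mu, sigma) are fitted by maximum
likelihood. Calibrated p-values and CIs shift by mu and widen by sigma.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .errors import CalibrationError
from .estimation import Z975, EffectEstimate


@dataclass
class NullDistribution:
    mu: float
    sigma: float
    n_controls: int


@dataclass
class CalibratedEstimate:
    uncalibrated: EffectEstimate
    rr: float
    ci95_low: float
    ci95_high: float
    p_value: float
    null: NullDistribution


def fit_null(
    estimates: list[tuple[float, float]],
    min_controls: int = 5,
) -> NullDistribution:
    """Maximum-likelihood empirical null from (theta_i, tau_i) NC estimates.

    Optimises over (mu, log sigma) with a sigma floor of 1e-8; deterministic.
    Fewer than ``min_controls`` estimable inputs raises CalibrationError
    (empirical calibration unavailable).
    """
    pairs = [(t, s) for t, s in estimates if np.isfinite(t) and np.isfinite(s)]
    if len(pairs) < min_controls:
        raise CalibrationError(
            f"need >= {min_controls} estimable negative-control estimates, got {len(pairs)}"
        )
    theta = np.array([p[0] for p in pairs])
    tau = np.array([p[1] for p in pairs])

    def negloglik(params: np.ndarray) -> float:
        mu, log_sigma = params
        var = np.exp(2 * log_sigma) + tau**2
        return float(0.5 * np.sum(np.log(2 * np.pi * var) + (theta - mu) ** 2 / var))

    start_sigma = max(float(theta.std()), 1e-3)
    res = optimize.minimize(
        negloglik,
        x0=np.array([float(theta.mean()), np.log(start_sigma)]),
        method="Nelder-Mead",
        options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 5000},
    )
    mu, log_sigma = res.x
    sigma = max(float(np.exp(log_sigma)), 1e-8)
    return NullDistribution(float(mu), sigma, len(pairs))


def calibrate(estimate: EffectEstimate, null: NullDistribution) -> CalibratedEstimate:
    """Calibrated p-value and CI for one effect estimate under the null.

    p = 2 * (1 - Phi(|theta - mu| / sqrt(sigma^2 + tau^2)));
    CI = exp(theta - mu +/- 1.96 * sqrt(sigma^2 + tau^2)).
    A not-estimable input propagates unchanged.
    """
    if not estimate.estimable:
        return CalibratedEstimate(estimate, np.nan, np.nan, np.nan, np.nan, null)
    total_se = float(np.sqrt(null.sigma**2 + estimate.se**2))
    shifted = estimate.log_rr - null.mu
    p = float(2 * stats.norm.sf(abs(shifted) / total_se))
    return CalibratedEstimate(
        estimate,
        float(np.exp(shifted)),
        float(np.exp(shifted - Z975 * total_se)),
        float(np.exp(shifted + Z975 * total_se)),
        p,
        null,
    )


def nc_diagnostic(
    estimates: list[EffectEstimate],
    threshold: float = 0.20,
) -> tuple[float, bool, int]:
    """Residual-bias diagnostic: the fraction of estimable negative controls
    whose uncalibrated 95% CI excludes 1.

    Passes iff the fraction is strictly below the threshold; on failure only
    calibrated estimates should be relied on downstream. Returns (fraction,
    passed, n_estimable); with zero estimable NCs the fraction is NaN and the
    diagnostic is not evaluable (reported as failed-to-evaluate upstream).
    """
    usable = [e for e in estimates if e.estimable]
    if not usable:
        return (float("nan"), False, 0)
    significant = sum(1 for e in usable if e.ci95_low > 1.0 or e.ci95_high < 1.0)
    fraction = significant / len(usable)
    return (fraction, fraction < threshold, len(usable))
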