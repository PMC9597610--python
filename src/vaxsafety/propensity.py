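"""Large-scale L1-regularised propensity model, greedy caliper matching, and
covariate balance.

The propensity model maximises the penalised log-likelihood
``l(beta) - lambda * sum |beta_j|`` (intercept unpenalised) with lambda chosen
by k-fold cross-validated held-out log-likelihood over a log-spaced grid
descending from lambda_max (the smallest penalty that zeroes every slope).
Features are standardised internally for the solver; coefficients are
returned on the raw covariate scale.

Matching is greedy variable-ratio (up to 1:4) within a caliper of 0.2 pooled
standard deviations of the logit propensity score. The smaller cohort is the
base side; when the target cohort is larger the orientation is reversed and
comparators are matched to up to four targets.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import KFold

from .cohorts import CovariateMatrix
from .errors import SingleArmError


@dataclass
class PSModel:
    coefficients: pd.Series  # indexed by covariate label, raw scale
    intercept: float
    penalty: float
    penalty_grid: np.ndarray = field(default_factory=lambda: np.empty(0))
    cv_loglik: np.ndarray = field(default_factory=lambda: np.empty(0))


@dataclass
class MatchedSet:
    base_id: int
    candidate_ids: list[int]
    reverse: bool = False


@dataclass
class BalanceTable:
    table: pd.DataFrame  # label, smd_pre, smd_post

    @property
    def max_abs_post(self) -> float:
        post = self.table["smd_post"].abs()
        return float(post.max()) if len(post) else 0.0


def _standardise(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    sd_safe = np.where(sd > 0, sd, 1.0)
    return (X - mean) / sd_safe, mean, sd_safe


def _fit_l1(Xs: np.ndarray, y: np.ndarray, lam: float, max_iter: int = 2000) -> tuple[np.ndarray, float]:
    """One penalised fit on standardised features; lam is on the summed
    log-likelihood scale (sklearn C = 1/lam)."""
    model = LogisticRegression(
        l1_ratio=1.0,
        C=1.0 / max(lam, 1e-12),
        solver="saga",
        fit_intercept=True,
        max_iter=max_iter,
        tol=1e-5,
        random_state=0,
    )
    model.fit(Xs, y)
    beta = model.coef_.ravel().copy()
    # The intercept is unpenalised, so given the slopes its optimum is the
    # exact 1-D MLE; saga leaves it short of that at large penalties.
    b0 = float(model.intercept_[0])
    offset = Xs @ beta
    for _ in range(50):
        p = 1.0 / (1.0 + np.exp(-(offset + b0)))
        grad = float(np.sum(y - p))
        hess = float(np.sum(p * (1 - p)))
        if hess <= 0:
            break
        step = grad / hess
        b0 += step
        if abs(step) < 1e-12:
            break
    return beta, b0


def _loglik(Xs: np.ndarray, y: np.ndarray, beta: np.ndarray, b0: float) -> float:
    eta = Xs @ beta + b0
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def fit_propensity_model(
    covariates: CovariateMatrix,
    arm: np.ndarray,
    lambda_grid: np.ndarray | list[float] | None = None,
    folds: int = 10,
    seed: int = 0,
    grid_size: int = 20,
) -> PSModel:
    """Fit the L1 propensity model for target-arm membership.

    ``arm`` is a boolean/0-1 array (1 = target) aligned with the covariate
    rows. With a single grid value cross-validation is skipped.
    """
    X = covariates.matrix.toarray() if sparse.issparse(covariates.matrix) else np.asarray(covariates.matrix)
    y = np.asarray(arm, dtype=float)
    if y.min() == y.max():
        raise SingleArmError("propensity model requires persons in both arms")
    Xs, mean, sd = _standardise(X)

    if lambda_grid is None:
        # glmnet-style: from the all-zero-slope penalty down four decades.
        ybar = y.mean()
        lam_max = float(np.max(np.abs(Xs.T @ (y - ybar)))) + 1e-12
        lambda_grid = np.geomspace(lam_max, lam_max * 1e-4, grid_size)
    lambda_grid = np.asarray(lambda_grid, dtype=float)

    cv_ll = np.full(lambda_grid.size, np.nan)
    if lambda_grid.size > 1:
        kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
        splits = list(kf.split(Xs))
        for i, lam in enumerate(lambda_grid):
            total = 0.0
            for train, test in splits:
                beta, b0 = _fit_l1(Xs[train], y[train], lam * len(train) / len(y))
                total += _loglik(Xs[test], y[test], beta, b0)
            cv_ll[i] = total
        best = int(np.nanargmax(cv_ll))
    else:
        best = 0
    lam = float(lambda_grid[best])
    beta_s, b0_s = _fit_l1(Xs, y, lam)

    beta_raw = beta_s / sd
    intercept = b0_s - float(np.sum(beta_raw * mean))
    coef = pd.Series(beta_raw, index=list(covariates.meta["label"]))
    return PSModel(coef, intercept, lam, lambda_grid, cv_ll)


def predict_logit(model: PSModel, covariates: CovariateMatrix) -> np.ndarray:
    """Logit propensity score per person; unseen covariates get coefficient 0."""
    labels = list(covariates.meta["label"])
    coef = model.coefficients.reindex(labels).fillna(0.0).to_numpy()
    X = covariates.matrix.toarray() if sparse.issparse(covariates.matrix) else np.asarray(covariates.matrix)
    return model.intercept + X @ coef


# --- greedy caliper matching ------------------------------------------------


def _find_avail(start: int, avail: np.ndarray, parent: np.ndarray, step: int) -> int:
    """First available index at or beyond ``start`` in direction ``step``
    (+1 right, -1 left), with path compression. Returns -1 if none."""
    n = avail.size
    path = []
    i = start
    while 0 <= i < n:
        if avail[i]:
            break
        path.append(i)
        i = parent[i]
    result = i if 0 <= i < n and avail[i] else -1
    hop = result if result >= 0 else (n if step > 0 else -1)
    for j in path:
        parent[j] = hop
    return result


def greedy_match(
    logits_target: pd.Series,
    logits_comparator: pd.Series,
    caliper_sd: float = 0.2,
    max_ratio: int = 4,
    seed: int = 0,
) -> list[MatchedSet]:
    """Greedy variable-ratio caliper matching on the logit propensity score.

    Inputs are person_id-indexed logit series per arm. The smaller arm is the
    base side (``reverse=True`` when the target arm is larger). The caliper is
    ``caliper_sd`` times the pooled SD of all logits; when all logits are
    equal the caliper is 0 and exact ties still match.

    The matched ratio is uniform: R = max(1, min(max_ratio,
    n_candidates // n_base)), and only matched sets that complete all R
    candidates are kept. A per-base "best effort" ratio would concentrate
    extra candidates wherever candidates are locally plentiful — exactly
    where the propensity distributions differ — and undo the covariate
    balance the matching exists to create; with a uniform completed ratio the
    matched candidate count is R times the base count in every propensity
    region, so matching preserves balance by construction. Matching proceeds
    in rounds 1..R: each round visits base subjects in a seeded random order
    and pairs each with its nearest unmatched candidate within the caliper
    (distance ties broken by lowest person_id). Base subjects with no match
    after round 1 are dropped; a base that fails a later round is dropped
    with its partial set (equivalent to trimming regions of poor candidate
    support); candidates are used at most once.
    """
    if len(logits_target) == 0 or len(logits_comparator) == 0:
        raise SingleArmError("matching requires non-empty arms")
    reverse = len(logits_target) > len(logits_comparator)
    base, cand = (logits_comparator, logits_target) if reverse else (logits_target, logits_comparator)

    pooled = np.concatenate([logits_target.to_numpy(float), logits_comparator.to_numpy(float)])
    caliper = caliper_sd * float(np.std(pooled))

    cdf = pd.DataFrame({"pid": cand.index.to_numpy(), "logit": cand.to_numpy(float)})
    cdf = cdf.sort_values(["logit", "pid"], kind="stable").reset_index(drop=True)
    clogit = cdf["logit"].to_numpy()
    cpid = cdf["pid"].to_numpy()
    nc = len(cdf)
    avail = np.ones(nc, dtype=bool)
    right_parent = np.arange(1, nc + 1)
    left_parent = np.arange(-1, nc - 1)

    base_pid = base.index.to_numpy()
    base_logit = base.to_numpy(float)
    rng = np.random.default_rng(seed)
    active = np.arange(len(base_pid))
    sets: dict[int, list[int]] = {}

    ratio = max(1, min(max_ratio, nc // len(base_pid)))
    for round_no in range(1, ratio + 1):
        order = active[rng.permutation(active.size)]
        survivors = []
        for bi in order:
            g = base_logit[bi]
            pos = int(np.searchsorted(clogit, g, side="left"))
            j_r = _find_avail(pos, avail, right_parent, +1)
            j_l = _find_avail(pos - 1, avail, left_parent, -1)
            d_r = clogit[j_r] - g if j_r >= 0 else np.inf
            d_l = g - clogit[j_l] if j_l >= 0 else np.inf
            d = min(d_l, d_r)
            pick = -1
            if np.isfinite(d):
                # Lowest person_id among ALL candidates at distance d: the
                # nearest run on each side can tie in floating point with
                # further runs (and with the other side), so walk outwards
                # while the distance is float-equal. Within one tied-logit
                # run, the first available position has the lowest id.
                jj = j_r
                while jj >= 0 and clogit[jj] - g == d:
                    if pick < 0 or cpid[jj] < cpid[pick]:
                        pick = jj
                    nxt = int(np.searchsorted(clogit, clogit[jj], side="right"))
                    jj = _find_avail(nxt, avail, right_parent, +1)
                jj = j_l
                while jj >= 0 and g - clogit[jj] == d:
                    run_start = int(np.searchsorted(clogit, clogit[jj], side="left"))
                    low = _find_avail(run_start, avail, right_parent, +1)
                    if 0 <= low <= jj and clogit[low] == clogit[jj]:
                        jj = low
                    if pick < 0 or cpid[jj] < cpid[pick]:
                        pick = jj
                    jj = _find_avail(run_start - 1, avail, left_parent, -1)
            if pick >= 0 and d <= caliper + 1e-12:
                avail[pick] = False
                sets.setdefault(int(base_pid[bi]), []).append(int(cpid[pick]))
                survivors.append(bi)
            # A base that fails any round is dropped (with its partial set).
        active = np.array(survivors, dtype=int)
        if active.size == 0 or not avail.any():
            break

    return [
        MatchedSet(pid, cands, reverse)
        for pid, cands in sets.items()
        if len(cands) == ratio
    ]


def matched_persons(sets: list[MatchedSet]) -> tuple[np.ndarray, np.ndarray]:
    """Person ids (base side, candidate side) appearing in the matched sets."""
    base = np.array(sorted(s.base_id for s in sets), dtype=np.int64)
    cand = np.array(sorted(pid for s in sets for pid in s.candidate_ids), dtype=np.int64)
    return base, cand


def matches_frame(sets: list[MatchedSet]) -> pd.DataFrame:
    rows = []
    for set_id, s in enumerate(sets):
        rows.append((set_id, "base", s.base_id))
        rows.extend((set_id, "candidate", pid) for pid in s.candidate_ids)
    return pd.DataFrame(rows, columns=["set_id", "role", "person_id"])


# --- covariate balance -------------------------------------------------------


def _smd(x_t: np.ndarray, x_c: np.ndarray, binary: bool) -> float:
    m_t, m_c = x_t.mean(), x_c.mean()
    if binary:
        v_t, v_c = m_t * (1 - m_t), m_c * (1 - m_c)
    else:
        v_t = x_t.var(ddof=1) if x_t.size > 1 else 0.0
        v_c = x_c.var(ddof=1) if x_c.size > 1 else 0.0
    denom = np.sqrt((v_t + v_c) / 2.0)
    if denom == 0:
        return 0.0 if m_t == m_c else np.nan
    return float((m_t - m_c) / denom)


def compute_smd(
    covariates: CovariateMatrix,
    target_ids: np.ndarray,
    comparator_ids: np.ndarray,
    pre: pd.DataFrame | None = None,
) -> BalanceTable:
    """Standardised mean differences per covariate for the given arm person
    sets: (mean_t - mean_c) / sqrt((var_t + var_c)/2), with p(1-p) variance
    for binary covariates. ``pre`` optionally supplies a previously computed
    table whose ``smd_post`` becomes this table's ``smd_pre``."""
    frame = covariates.to_frame()
    X_t = frame.loc[frame.index.isin(set(target_ids))]
    X_c = frame.loc[frame.index.isin(set(comparator_ids))]
    binary = (covariates.meta["kind"] == "binary").to_numpy()
    smds = [
        _smd(X_t.iloc[:, j].to_numpy(), X_c.iloc[:, j].to_numpy(), bool(binary[j]))
        for j in range(frame.shape[1])
    ]
    table = pd.DataFrame({"label": list(covariates.meta["label"]), "smd_post": smds})
    table["smd_pre"] = pre["smd_post"].to_numpy() if pre is not None else np.nan
    return BalanceTable(table[["label", "smd_pre", "smd_post"]])


def balance_gate(balance: BalanceTable, threshold: float = 0.1) -> tuple[bool, list[str]]:
    """Pass iff every post-match |SMD| is strictly below the threshold.

    Returns (passed, offending covariate labels); an undefined SMD (NaN from
    zero variances with unequal means) counts as a violation.
    """
    post = balance.table["smd_post"]
    bad = post.isna() | (post.abs() >= threshold)
    return (not bool(bad.any()), list(balance.table.loc[bad, "label"]))
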