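"""Forward-recurrence Weibull AFT regression with a profiled common shape.

The observed (capture-to-drop-off) time ``V`` of a tick in a prevalent
cohort follows the equilibrium law of its Weibull whole attachment time,
``f_V(v) = exp(-(v/lambda)^k) / (lambda * Gamma(1 + 1/k))``.  The model is
an accelerated failure time regression on the scale,

    log lambda_i = x_i' beta,

with a single shape ``k`` shared by all groups; because the scale enters
both ``V`` and ``T`` identically, the fitted coefficients describe the
whole attachment times as well, and the whole/observed mean ratio
``R(k)`` depends only on the shape.

Estimation is by profile likelihood: for each candidate shape the
coefficient vector is maximised by Newton iterations (the log-likelihood
is strictly concave in ``beta``), and a one-dimensional bounded search
over ``log k`` maximises the profile.  The shape's standard error comes
from the profile curvature; the covariance of ``(beta, log k)`` is a
cluster-robust sandwich (bread = observed information, meat = summed
per-host scores), since ticks sharing a host are correlated.

Observed times are bin midpoints (0.5, 1.5, ... days).  By default they
are treated as exact ("midpoint"); an interval-censored likelihood using
the bin probabilities ``F_V(d) - F_V(d-1)`` is available as
``time_convention="interval"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize, minimize_scalar
from scipy.special import digamma, gammainc, gammaln
from scipy.stats import norm

from .attachment import mean_ratio, mean_ratio_ci

__all__ = [
    "ModelSpec",
    "AFTFit",
    "build_design",
    "fit_forward_aft",
    "predict_group_means",
    "cell_log_scale_estimates",
    "sensitivity_merge_day12",
    "fit_report",
]

STAGE_LEVELS = ("larva", "nymph", "female", "male")
SEASON_LEVELS = ("spring", "summer", "autumn")

_LOG_SHAPE_BOUNDS = (np.log(0.3), np.log(30.0))


@dataclass(frozen=True)
class ModelSpec:
    """Covariate structure of the attachment-time regression.

    ``covariates`` is one of ``"1"`` (intercept only), ``"stage"``,
    ``"stage+season"`` or ``"stage*season"`` (main effects plus
    interaction, the study's full model).  Treatment coding against the
    ``reference`` levels; the reported group means are coding-invariant.
    """

    covariates: str = "stage*season"
    reference: tuple = ("larva", "spring")
    time_convention: str = "midpoint"  # or "interval"

    def __post_init__(self) -> None:
        if self.covariates not in ("1", "stage", "stage+season", "stage*season"):
            raise ValueError(f"unknown covariate set {self.covariates!r}")
        if self.time_convention not in ("midpoint", "interval"):
            raise ValueError(f"unknown time convention {self.time_convention!r}")

    @property
    def uses_stage(self) -> bool:
        return self.covariates != "1"

    @property
    def uses_season(self) -> bool:
        return self.covariates in ("stage+season", "stage*season")

    @property
    def interaction(self) -> bool:
        return self.covariates == "stage*season"


def _levels(values, fixed, reference):
    levels = [x for x in fixed if x in set(values)]
    unknown = sorted(set(values) - set(fixed))
    if unknown:
        raise ValueError(f"unknown levels {unknown}; expected subset of {fixed}")
    if reference in levels:
        levels = [reference] + [x for x in levels if x != reference]
    return levels


def build_design(records: pd.DataFrame, spec: ModelSpec):
    """Treatment-coded design matrix with intercept, plus cell labels.

    Returns ``(X, names, cells, cell_rows)`` where ``cells`` is the list
    of observed groups (``(stage,)`` or ``(stage, season)`` tuples) and
    ``cell_rows`` maps each cell to its design row, for group predictions.
    """
    if records.empty:
        raise ValueError("records must be non-empty")
    n = len(records)
    cols = [np.ones(n)]
    names = ["intercept"]
    ref_stage, ref_season = spec.reference

    stage_levels = season_levels = []
    if spec.uses_stage:
        stage_levels = _levels(records["stage"], STAGE_LEVELS, ref_stage)
        for s in stage_levels[1:]:
            cols.append((records["stage"] == s).to_numpy(float))
            names.append(f"stage[{s}]")
    if spec.uses_season:
        season_levels = _levels(records["season"], SEASON_LEVELS, ref_season)
        for s in season_levels[1:]:
            cols.append((records["season"] == s).to_numpy(float))
            names.append(f"season[{s}]")
    if spec.interaction:
        for st in stage_levels[1:]:
            for se in season_levels[1:]:
                cols.append(((records["stage"] == st) &
                             (records["season"] == se)).to_numpy(float))
                names.append(f"stage[{st}]:season[{se}]")
    X = np.column_stack(cols)

    if spec.uses_season:
        cells = sorted(set(zip(records["stage"], records["season"])),
                       key=lambda c: (STAGE_LEVELS.index(c[0]),
                                      SEASON_LEVELS.index(c[1])))
    elif spec.uses_stage:
        cells = sorted({(s,) for s in records["stage"]},
                       key=lambda c: STAGE_LEVELS.index(c[0]))
    else:
        cells = [()]

    cell_rows = {}
    for cell in cells:
        row = np.zeros(len(names))
        row[0] = 1.0
        for j, name in enumerate(names):
            if cell and name == f"stage[{cell[0]}]":
                row[j] = 1.0
            if len(cell) == 2 and name == f"season[{cell[1]}]":
                row[j] = 1.0
            if len(cell) == 2 and name == f"stage[{cell[0]}]:season[{cell[1]}]":
                row[j] = 1.0
        cell_rows[cell] = row
    return X, names, cells, cell_rows


@dataclass
class AFTFit:
    """Fitted forward-recurrence AFT model."""

    beta: np.ndarray
    beta_names: list
    shape_hat: float
    shape_se: float
    cov_sandwich: np.ndarray  # over (beta, log shape)
    cov_naive: np.ndarray
    loglik: float
    n_ticks: float
    n_clusters: int
    converged: bool
    robust: str  # "cluster" or "naive"
    spec: ModelSpec
    cells: list
    cell_rows: dict
    grad_norm: float = np.nan

    def mean_ratio(self) -> float:
        return mean_ratio(self.shape_hat)

    def mean_ratio_ci(self, level: float = 0.95):
        return mean_ratio_ci(self.shape_hat, self.shape_se, level)


# ---------------------------------------------------------------------------
# likelihood internals

def _row_loglik_midpoint(v, X, k, beta):
    eta = X @ beta
    logz = k * (np.log(v) - eta)
    return -np.exp(logz) - eta - gammaln(1.0 + 1.0 / k)


def _row_loglik_interval(v, X, k, beta):
    # v is the bin midpoint d - 0.5; the bin is (d-1, d]
    eta = X @ beta
    lam = np.exp(eta)
    hi = gammainc(1.0 / k, ((v + 0.5) / lam) ** k)
    lo = gammainc(1.0 / k, (np.maximum(v - 0.5, 0.0) / lam) ** k)
    return np.log(np.maximum(hi - lo, 1e-300))


def _newton_beta(v, X, w, k, beta0):
    """Maximise the midpoint log-likelihood over beta at fixed shape.

    Strictly concave: d2ll/deta2 = -k^2 z < 0, so damped Newton converges
    from any start.
    """
    beta = beta0.copy()
    logv = np.log(v)
    ll = np.sum(w * _row_loglik_midpoint(v, X, k, beta))
    for _ in range(200):
        eta = X @ beta
        z = np.exp(np.clip(k * (logv - eta), -700, 700))
        score = X.T @ (w * (k * z - 1.0))
        W = w * (k * k * z)
        H = (X * W[:, None]).T @ X
        try:
            step = np.linalg.solve(H, score)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, score, rcond=None)[0]
        t = 1.0
        for _ in range(60):
            cand = beta + t * step
            llc = np.sum(w * _row_loglik_midpoint(v, X, k, cand))
            if llc >= ll - 1e-13:
                break
            t *= 0.5
        beta, ll_new = cand, llc
        if abs(ll_new - ll) < 1e-12 * (1 + abs(ll)) and np.max(np.abs(t * step)) < 1e-10:
            ll = ll_new
            break
        ll = ll_new
    return beta, ll


def _maximise_beta(v, X, w, k, beta0, convention):
    if convention == "midpoint":
        return _newton_beta(v, X, w, k, beta0)
    res = minimize(
        lambda b: -np.sum(w * _row_loglik_interval(v, X, k, b)),
        beta0, method="BFGS", options={"gtol": 1e-9, "maxiter": 500})
    return res.x, -res.fun


def fit_forward_aft(records: pd.DataFrame, spec: ModelSpec | None = None,
                    cluster: str | None = "host_id",
                    weight: str | None = None) -> AFTFit:
    """Fit the forward-recurrence AFT model by profile likelihood.

    ``records`` holds one tick per row (or one day-bin per row with an
    integer ``weight`` column, e.g. ``"count"``, for published aggregate
    tables).  ``cluster`` names the host-id column for the sandwich
    covariance; aggregated input without hosts passes ``cluster=None``
    and the covariance degrades to the model-based one (flagged
    ``robust="naive"``).
    """
    spec = spec or ModelSpec()
    if records.empty:
        raise ValueError("records must be non-empty")
    v = records["observed_day"].to_numpy(float)
    if np.any(~np.isfinite(v)) or np.any(v <= 0):
        raise ValueError("all observed times must be positive and finite")
    if np.unique(v).size == 1:
        raise ValueError("degenerate data: all observed times are equal; "
                         "the shape parameter is not identifiable")
    w = (records[weight].to_numpy(float) if weight is not None
         else np.ones(len(records)))
    if np.any(w <= 0):
        raise ValueError("weights must be positive")

    X, names, cells, cell_rows = build_design(records, spec)
    p = X.shape[1]

    # profile likelihood over log-shape, warm-starting beta between calls
    beta_ws = {"beta": np.zeros(p)}
    beta_ws["beta"][0] = np.log(np.average(v, weights=w))

    def profile_nll(logk):
        k = float(np.exp(logk))
        beta, ll = _maximise_beta(v, X, w, k, beta_ws["beta"], spec.time_convention)
        beta_ws["beta"] = beta
        return -ll

    res = minimize_scalar(profile_nll, bounds=_LOG_SHAPE_BOUNDS,
                          method="bounded", options={"xatol": 1e-8})
    logk_hat = float(res.x)
    shape_hat = float(np.exp(logk_hat))
    beta_hat, loglik = _maximise_beta(v, X, w, shape_hat, beta_ws["beta"],
                                      spec.time_convention)

    # shape SE from profile curvature on the log scale
    h = 1e-3
    pl0, plp, plm = (-res.fun, -profile_nll(logk_hat + h), -profile_nll(logk_hat - h))
    curv = (plp - 2 * pl0 + plm) / h**2
    var_logk = -1.0 / curv if curv < 0 else np.nan
    shape_se = float(shape_hat * np.sqrt(var_logk)) if np.isfinite(var_logk) else np.nan

    theta = np.append(beta_hat, logk_hat)
    row_ll = _make_row_loglik(v, X, spec.time_convention)
    U = _numeric_row_scores(row_ll, theta)          # n x (p+1), unweighted
    Uw = U * w[:, None]
    grad = Uw.sum(axis=0)
    A = -_numeric_hessian(lambda th: float(np.sum(w * row_ll(th))), theta)

    if cluster is not None and cluster in records.columns:
        groups = records[cluster].to_numpy()
        meat = np.zeros((p + 1, p + 1))
        for g in pd.unique(groups):
            s = Uw[groups == g].sum(axis=0)
            meat += np.outer(s, s)
        n_clusters = int(pd.unique(groups).size)
        robust = "cluster"
    else:
        meat = Uw.T @ Uw
        n_clusters = len(records)
        robust = "naive"

    Ainv = np.linalg.pinv(A)
    cov_sandwich = Ainv @ meat @ Ainv
    cov_sandwich = 0.5 * (cov_sandwich + cov_sandwich.T)
    cov_naive = 0.5 * (Ainv + Ainv.T)

    grad_norm = float(np.linalg.norm(grad))
    converged = bool(res.success) and np.isfinite(loglik) and \
        grad_norm < 1e-3 * max(1.0, float(np.sum(w)))
    return AFTFit(
        beta=beta_hat, beta_names=names, shape_hat=shape_hat, shape_se=shape_se,
        cov_sandwich=cov_sandwich, cov_naive=cov_naive, loglik=float(loglik),
        n_ticks=float(np.sum(w)), n_clusters=n_clusters, converged=converged,
        robust=robust, spec=spec, cells=cells, cell_rows=cell_rows,
        grad_norm=grad_norm)


def _make_row_loglik(v, X, convention):
    if convention == "midpoint":
        return lambda th: _row_loglik_midpoint(v, X, float(np.exp(th[-1])), th[:-1])
    return lambda th: _row_loglik_interval(v, X, float(np.exp(th[-1])), th[:-1])


def _numeric_row_scores(row_ll, theta, h: float = 1e-6):
    n = len(row_ll(theta))
    U = np.empty((n, len(theta)))
    for j in range(len(theta)):
        hj = h * max(1.0, abs(theta[j]))
        tp, tm = theta.copy(), theta.copy()
        tp[j] += hj
        tm[j] -= hj
        U[:, j] = (row_ll(tp) - row_ll(tm)) / (2 * hj)
    return U


def _numeric_hessian(f, theta, h: float = 1e-4):
    d = len(theta)
    H = np.empty((d, d))
    hs = [h * max(1.0, abs(t)) for t in theta]
    f0 = f(theta)
    for i in range(d):
        for j in range(i, d):
            tpp, tpm, tmp, tmm = (theta.copy() for _ in range(4))
            tpp[[i, j]] += [hs[i], hs[j]]
            tmm[[i, j]] -= [hs[i], hs[j]]
            if i == j:
                H[i, i] = (f(tpp) - 2 * f0 + f(tmm)) / (hs[i] * hs[i])
            else:
                tpm[i] += hs[i]
                tpm[j] -= hs[j]
                tmp[i] -= hs[i]
                tmp[j] += hs[j]
                H[i, j] = H[j, i] = (f(tpp) - f(tpm) - f(tmp) + f(tmm)) / \
                    (4 * hs[i] * hs[j])
    return H


# ---------------------------------------------------------------------------
# predictions on the observed and whole scales

def predict_group_means(fit: AFTFit, groups=None, level: float = 0.95) -> pd.DataFrame:
    """Per-group mean observed and whole attachment times with delta CIs.

    For group g with scale ``lambda_g = exp(x_g' beta)``:
    ``E[V]_g = lambda_g Gamma(1+2/k)/(2 Gamma(1+1/k))`` and
    ``E[T]_g = R(k) E[V]_g = lambda_g Gamma(1+1/k)``; the whole/observed
    ratio is the same for every group because the shape is shared.
    """
    groups = list(groups) if groups is not None else fit.cells
    k = fit.shape_hat
    z = norm.ppf(0.5 + level / 2.0)
    g1 = gammaln(1.0 + 1.0 / k)
    g2 = gammaln(1.0 + 2.0 / k)
    dlogV_dlogk = (digamma(1.0 + 1.0 / k) - 2.0 * digamma(1.0 + 2.0 / k)) / k
    dlogT_dlogk = -digamma(1.0 + 1.0 / k) / k

    rows = []
    for cell in groups:
        cell = tuple(cell) if not isinstance(cell, tuple) else cell
        if cell not in fit.cell_rows:
            raise ValueError(f"unknown group {cell!r}; fitted groups: {fit.cells}")
        x = fit.cell_rows[cell]
        eta = float(x @ fit.beta)
        log_ev = eta + g2 - g1 - np.log(2.0)
        log_et = eta + g1
        gv = np.append(x, dlogV_dlogk)
        gt = np.append(x, dlogT_dlogk)
        se_v = float(np.sqrt(max(gv @ fit.cov_sandwich @ gv, 0.0)))
        se_t = float(np.sqrt(max(gt @ fit.cov_sandwich @ gt, 0.0)))
        rows.append({
            **({"stage": cell[0]} if cell else {}),
            **({"season": cell[1]} if len(cell) == 2 else {}),
            "scale": float(np.exp(eta)),
            "observed_mean": float(np.exp(log_ev)),
            "observed_lo": float(np.exp(log_ev - z * se_v)),
            "observed_hi": float(np.exp(log_ev + z * se_v)),
            "whole_mean": float(np.exp(log_et)),
            "whole_lo": float(np.exp(log_et - z * se_t)),
            "whole_hi": float(np.exp(log_et + z * se_t)),
        })
    return pd.DataFrame(rows)


def cell_log_scale_estimates(fit: AFTFit):
    """Cell labels, log-scale estimates and their covariance.

    Differences of log scales equal differences of log whole-time means
    (the shared Gamma factor cancels), so these feed the ratio contrasts.
    """
    L = np.array([fit.cell_rows[c] for c in fit.cells])
    log_means = L @ fit.beta
    cov = L @ fit.cov_sandwich[:-1, :-1] @ L.T
    return list(fit.cells), log_means, 0.5 * (cov + cov.T)


def sensitivity_merge_day12(records: pd.DataFrame) -> pd.DataFrame:
    """Assign a common observed time of 1 day to day-1 and day-2 drop-offs.

    Sensitivity analysis for the day-1 deficit: every record observed at
    0.5 or 1.5 days is recoded to 1.0 day; everything else is unchanged.
    """
    out = records.copy()
    out.loc[out["observed_day"].isin([0.5, 1.5]), "observed_day"] = 1.0
    return out


def fit_report(fit: AFTFit, level: float = 0.95) -> dict:
    """JSON-able report of a fitted attachment-time model."""
    est, lo, hi = fit.mean_ratio_ci(level)
    means = predict_group_means(fit, level=level)
    return {
        "model": {"covariates": fit.spec.covariates,
                  "time_convention": fit.spec.time_convention,
                  "robust": fit.robust},
        "n_ticks": fit.n_ticks,
        "n_clusters": fit.n_clusters,
        "converged": fit.converged,
        "loglik": fit.loglik,
        "shape": {"estimate": fit.shape_hat, "se": fit.shape_se},
        "beta": dict(zip(fit.beta_names, map(float, fit.beta))),
        "mean_ratio": {"estimate": est, "lo": lo, "hi": hi, "level": level},
        "group_means": means.to_dict(orient="records"),
    }
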