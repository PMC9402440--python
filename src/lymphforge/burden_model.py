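"""Depth-corrected mutation burden and the age x cell-type mixed model.

Sequencing depth limits mutation recall, so raw per-colony burdens are
corrected by an asymptotic depth-response curve

    f(x) = b0 + b1 (1 - exp(-exp(lrc) x))

fitted to reference colonies, and each burden is rescaled to a common
reference depth (30x) as n * f(30)/f(depth).

Adjusted burdens are then modelled with a Gaussian linear mixed-effects
model: age and cell type as fixed effects with their interaction (one
intercept and one slope per cell type), a donor-by-cell-type random
intercept, and a *separate residual variance per cell type* (the
variance of memory-cell burdens within a donor is an order of magnitude
above that of stem cells). The fit is by direct maximum likelihood with
the fixed effects profiled out by generalised least squares; the
compound-symmetric group covariance sigma_t^2 I + sigma_d^2 J admits a
closed-form inverse and determinant, so each likelihood evaluation is
linear in the number of colonies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

REF_DEPTH = 30.0
MAX_REFERENCE_DEPTH = 50.0  # colonies above this are excluded from the reference fit
_MIN_LOG_SD = np.log(1e-6)


class FitError(RuntimeError):
    """Raised when an optimiser fails; carries the best iterate found."""

    def __init__(self, message: str, best=None):
        super().__init__(message)
        self.best = best


@dataclass
class DepthResponse:
    """Asymptotic burden-vs-depth curve y = b0 + b1 (1 - exp(-exp(lrc) x))."""

    b0: float
    b1: float
    lrc: float
    converged: bool = True
    rss: float = float("nan")

    def __post_init__(self) -> None:
        if self.b1 < 0:
            raise ValueError("b1 must be non-negative (curve must be non-decreasing)")

    def predict(self, depth) -> np.ndarray:
        x = np.asarray(depth, dtype=float)
        return self.b0 + self.b1 * (1.0 - np.exp(-np.exp(self.lrc) * x))


def fit_depth_response(depths: np.ndarray, burdens: np.ndarray) -> DepthResponse:
    """Least-squares fit of the asymptotic depth-response curve.

    Requires at least four distinct depths. A constant response is
    handled degenerately as b1 = 0, b0 = mean(burden).
    """
    x = np.asarray(depths, dtype=float)
    y = np.asarray(burdens, dtype=float)
    if (x <= 0).any():
        raise ValueError("depths must be positive")
    if len(np.unique(x)) < 4:
        raise ValueError("need >= 4 distinct depths to fit three parameters")
    if np.ptp(y) == 0:
        return DepthResponse(b0=float(y[0]), b1=0.0, lrc=0.0, rss=0.0)

    def curve(x, b0, b1, lrc):
        return b0 + b1 * (1.0 - np.exp(-np.exp(lrc) * x))

    # moment-style initialisation: saturation near max(y), rate from the
    # depth at which half the range is reached
    b1_init = max(np.ptp(y), 1e-6)
    lrc_init = np.log(1.0 / max(np.median(x), 1.0))
    best = DepthResponse(b0=float(y.min()), b1=b1_init, lrc=lrc_init, converged=False)
    try:
        popt, _ = optimize.curve_fit(
            curve,
            x,
            y,
            p0=[y.min(), b1_init, lrc_init],
            bounds=([-np.inf, 0.0, -20.0], [np.inf, np.inf, 20.0]),
            maxfev=20_000,
        )
    except RuntimeError as exc:
        raise FitError(f"depth-response fit did not converge: {exc}", best=best) from exc
    rss = float(np.sum((curve(x, *popt) - y) ** 2))
    return DepthResponse(b0=float(popt[0]), b1=float(popt[1]), lrc=float(popt[2]), rss=rss)


def adjust_to_reference_depth(
    n: float, depth: float, dr: DepthResponse, ref_depth: float = REF_DEPTH
) -> float:
    """Rescale a burden observed at ``depth`` to the reference depth.

    adjusted = n * f(ref_depth) / f(depth); exact identity at the
    reference depth, and preserves zero burdens.
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    f_obs = float(dr.predict(depth))
    if f_obs <= 0:
        raise ValueError(f"fitted curve non-positive at depth {depth}")
    return float(n) * float(dr.predict(ref_depth)) / f_obs


# ---------------------------------------------------------------------------
# linear mixed model with per-cell-type residual variances


def _group_loglik(r: np.ndarray, s2_t: float, s2_d: float) -> float:
    """Gaussian log-density of residuals under sigma_t^2 I + sigma_d^2 J."""
    n = len(r)
    denom = s2_t + n * s2_d
    rs = r.sum()
    quad = (r @ r) / s2_t - (s2_d / (s2_t * denom)) * rs * rs
    logdet = (n - 1) * np.log(s2_t) + np.log(denom)
    return -0.5 * (n * np.log(2 * np.pi) + logdet + quad)


def _gls_beta(
    X: np.ndarray,
    y: np.ndarray,
    group_idx: list[np.ndarray],
    group_type: list[int],
    s2_types: np.ndarray,
    s2_d: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Profiled GLS fixed effects and their covariance."""
    p = X.shape[1]
    XtVX = np.zeros((p, p))
    XtVy = np.zeros(p)
    for idx, t in zip(group_idx, group_type):
        Xg, yg = X[idx], y[idx]
        s2_t = s2_types[t]
        n = len(idx)
        denom = s2_t + n * s2_d
        # V^-1 z = z/s2_t - (s2_d/(s2_t*denom)) * sum(z)
        c = s2_d / (s2_t * denom)
        Xs, ys = Xg.sum(axis=0), yg.sum()
        XtVX += Xg.T @ Xg / s2_t - c * np.outer(Xs, Xs)
        XtVy += Xg.T @ yg / s2_t - c * Xs * ys
    cov = np.linalg.pinv(XtVX)
    return cov @ XtVy, cov


def _fit_lmm(
    y: np.ndarray,
    X: np.ndarray,
    group_idx: list[np.ndarray],
    group_type: list[int],
    obs_type: np.ndarray,
    n_types: int,
    heteroscedastic: bool = True,
    random_intercept: bool = True,
) -> dict:
    """ML fit of the mixed model; fixed effects profiled by GLS."""
    n_var = (n_types if heteroscedastic else 1) + (1 if random_intercept else 0)

    def unpack(theta):
        theta = np.clip(theta, _MIN_LOG_SD, 20.0)
        if heteroscedastic:
            s2_types = np.exp(2 * theta[:n_types])
            k = n_types
        else:
            s2_types = np.full(n_types, np.exp(2 * theta[0]))
            k = 1
        s2_d = np.exp(2 * theta[k]) if random_intercept else 0.0
        return s2_types, s2_d

    def negloglik(theta):
        s2_types, s2_d = unpack(theta)
        beta, _ = _gls_beta(X, y, group_idx, group_type, s2_types, s2_d)
        r = y - X @ beta
        ll = 0.0
        for idx, t in zip(group_idx, group_type):
            ll += _group_loglik(r[idx], s2_types[t], s2_d)
        return -ll

    # initialise from OLS residual scales
    beta0, *_ = np.linalg.lstsq(X, y, rcond=None)
    r0 = y - X @ beta0
    if heteroscedastic:
        init = [
            np.log(max(np.std(r0[obs_type == t]), 1e-3)) for t in range(n_types)
        ]
    else:
        init = [np.log(max(np.std(r0), 1e-3))]
    if random_intercept:
        gmeans = np.array([r0[idx].mean() for idx in group_idx])
        init.append(np.log(max(np.std(gmeans), 1e-3)))
    res = optimize.minimize(
        negloglik,
        np.array(init),
        method="Nelder-Mead",
        options={"maxiter": 4000, "xatol": 1e-6, "fatol": 1e-8},
    )
    s2_types, s2_d = unpack(res.x)
    beta, cov = _gls_beta(X, y, group_idx, group_type, s2_types, s2_d)
    return {
        "beta": beta,
        "cov": cov,
        "resid_sd": np.sqrt(s2_types),
        "donor_sd": np.sqrt(s2_d),
        "loglik": -res.fun,
        "converged": bool(res.success),
    }


@dataclass
class BurdenFit:
    """ML estimates of the age x cell-type burden model."""

    cell_types: list[str]
    slopes: pd.DataFrame  # cell_type, slope, lo95, hi95
    offsets: pd.DataFrame  # cell_type, offset vs baseline, lo95, hi95
    resid_sd: dict[str, float]
    donor_sd: float
    interaction_p: float
    loglik: float
    converged: bool
    baseline: str = "HSPC"
    _internals: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        for tab in (self.slopes, self.offsets):
            inside = (tab["lo95"] <= tab.iloc[:, 1] + 1e-9) & (
                tab.iloc[:, 1] <= tab["hi95"] + 1e-9
            )
            if not inside.all():
                raise ValueError("confidence interval does not contain point estimate")


def _design(table: pd.DataFrame, cell_types: list[str], interaction: bool) -> np.ndarray:
    """Cell-means design: per-type intercepts, then per-type (or common) slopes."""
    n = len(table)
    K = len(cell_types)
    t_idx = table["cell_type"].map({t: i for i, t in enumerate(cell_types)}).to_numpy()
    age = table["age"].to_numpy(dtype=float)
    if interaction:
        X = np.zeros((n, 2 * K))
        X[np.arange(n), t_idx] = 1.0
        X[np.arange(n), K + t_idx] = age
    else:
        X = np.zeros((n, K + 1))
        X[np.arange(n), t_idx] = 1.0
        X[:, K] = age
    return X


def fit_burden_age_model(
    table: pd.DataFrame,
    burden_col: str = "burden",
    baseline: str = "HSPC",
) -> BurdenFit:
    """Fit the mixed-effects age model to a per-colony burden table.

    ``table`` needs columns donor, age, cell_type and the burden. The
    model has per-cell-type intercepts and age slopes (the interaction),
    a donor-by-cell-type random intercept, and per-cell-type residual
    variances; estimation is by maximum likelihood. Reported: per-type
    slopes and intercept offsets relative to ``baseline`` with Wald 95%
    CIs, variance components, and a likelihood-ratio p-value for the
    age x cell-type interaction.
    """
    for col in ("donor", "age", "cell_type", burden_col):
        if col not in table.columns:
            raise ValueError(f"missing column {col!r}")
    if table["donor"].nunique() < 2:
        raise ValueError("unidentifiable design: need >= 2 donors")
    if table["age"].nunique() < 2:
        raise ValueError("unidentifiable design: need >= 2 distinct ages")
    cell_types = sorted(table["cell_type"].unique())
    if len(cell_types) < 2:
        raise ValueError("unidentifiable design: need >= 2 cell types")
    if baseline not in cell_types:
        baseline = cell_types[0]

    y = table[burden_col].to_numpy(dtype=float)
    obs_type = table["cell_type"].map({t: i for i, t in enumerate(cell_types)}).to_numpy()
    groups = table.groupby(["donor", "cell_type"], sort=True).indices
    group_idx = [np.asarray(v) for v in groups.values()]
    group_type = [cell_types.index(k[1]) for k in groups.keys()]
    K = len(cell_types)

    X_full = _design(table, cell_types, interaction=True)
    fit = _fit_lmm(y, X_full, group_idx, group_type, obs_type, K)

    X_null = _design(table, cell_types, interaction=False)
    fit_null = _fit_lmm(y, X_null, group_idx, group_type, obs_type, K)
    lrt = max(2.0 * (fit["loglik"] - fit_null["loglik"]), 0.0)
    interaction_p = float(stats.chi2.sf(lrt, df=K - 1))

    # Wald intervals with containment degrees of freedom: age and the
    # cell-type contrasts vary at the donor level, so the reference t
    # has (#donors - 2) df; a normal quantile badly undercovers with
    # the handful of donors typical of colony studies.
    df_t = max(table["donor"].nunique() - 2, 1)
    z = stats.t.ppf(0.975, df_t)
    beta, cov = fit["beta"], fit["cov"]
    slopes = pd.DataFrame(
        {
            "cell_type": cell_types,
            "slope": beta[K : 2 * K],
            "lo95": beta[K : 2 * K] - z * np.sqrt(np.diag(cov)[K : 2 * K]),
            "hi95": beta[K : 2 * K] + z * np.sqrt(np.diag(cov)[K : 2 * K]),
        }
    )
    b_idx = cell_types.index(baseline)
    rows = []
    for i, t in enumerate(cell_types):
        diff = beta[i] - beta[b_idx]
        var = cov[i, i] + cov[b_idx, b_idx] - 2 * cov[i, b_idx]
        se = np.sqrt(max(var, 0.0))
        rows.append({"cell_type": t, "offset": diff, "lo95": diff - z * se, "hi95": diff + z * se})
    offsets = pd.DataFrame(rows)

    return BurdenFit(
        cell_types=cell_types,
        slopes=slopes,
        offsets=offsets,
        resid_sd={t: float(s) for t, s in zip(cell_types, fit["resid_sd"])},
        donor_sd=float(fit["donor_sd"]),
        interaction_p=interaction_p,
        loglik=float(fit["loglik"]),
        converged=fit["converged"],
        baseline=baseline,
        _internals={
            "y": y,
            "X": X_full,
            "group_idx": group_idx,
            "group_type": group_type,
            "obs_type": obs_type,
            "n_types": K,
        },
    )


def variance_heterogeneity_test(fit: BurdenFit) -> tuple[float, float]:
    """LRT of per-cell-type residual variances against a common variance.

    Returns ``(statistic, p)``; the statistic is chi-square with
    (#cell types - 1) degrees of freedom under the null.
    """
    ints = fit._internals
    if not ints:
        raise ValueError("fit does not carry the data needed for the nested refit")
    homo = _fit_lmm(
        ints["y"],
        ints["X"],
        ints["group_idx"],
        ints["group_type"],
        ints["obs_type"],
        ints["n_types"],
        heteroscedastic=False,
    )
    lrt = max(2.0 * (fit.loglik - homo["loglik"]), 0.0)
    p = float(stats.chi2.sf(lrt, df=ints["n_types"] - 1))
    return float(lrt), p


def reference_depth_fit(
    burden_table: pd.DataFrame,
    depth_col: str = "mean_depth",
    burden_col: str = "burden",
    max_depth: float = MAX_REFERENCE_DEPTH,
) -> DepthResponse:
    """Fit the depth-response curve on reference colonies (<= 50x)."""
    sub = burden_table[burden_table[depth_col] <= max_depth]
    return fit_depth_response(sub[depth_col].to_numpy(), sub[burden_col].to_numpy())
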