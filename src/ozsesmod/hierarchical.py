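"""Two-level normal Bayesian hierarchical meta-regression (stage 2).

Stage-1 ZCTA estimates are pooled under the model

    beta_z | theta_z, V_z  ~  N(theta_z, V_z)
    theta_z | a0, g, tau^2 ~  N(a0 + sum_j g_j X_zj, tau^2)

with a noninformative prior: flat on the coefficients and (by default) flat
on the between-ZCTA SD tau over [0, tau_max].  For fixed tau the coefficient
posterior is the generalized-least-squares normal with weights
1/(V_z + tau^2); the marginal posterior of tau is available in closed form
up to a constant and is integrated numerically over an adaptive grid (no
Monte Carlo).  Reported coefficient means/SDs are the tau-mixture moments.

Second-stage designs follow the study's conventions:

* overall combined model: one indicator column per city, no intercept
  (equivalent to intercept + two city indicators);
* combined effect-modification model: intercept, indicators for the
  non-reference cities, and the SES modifier (a 0/1 flag, or raw polynomial
  columns x, x^2, ..., x^degree of a continuous indicator);
* city-specific model: intercept (+ modifier columns), rows of one city.

Odds ratios are reported per 25 ppb ozone: OR = exp(25 * x' g), with
Wald-style 95% posterior intervals from the full coefficient posterior
covariance.  A coefficient is "significant" when |estimate / posterior SD|
is strictly greater than 1.96.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Stage2Error",
    "build_second_stage_design",
    "TwoLevelNormalMeta",
    "MetaResults",
    "fit_two_level_normal",
    "wald_significant",
    "zcta_mean_or",
]

Z_CRIT = 1.96


class Stage2Error(ValueError):
    pass


def _check_full_rank(X: pd.DataFrame) -> None:
    mat = X.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(mat)
    if rank < mat.shape[1]:
        # name the offending columns via pivoted QR
        from scipy.linalg import qr

        _, _, piv = qr(mat, mode="economic", pivoting=True)
        bad = [X.columns[i] for i in piv[rank:]]
        raise Stage2Error(f"second-stage design is rank deficient; collinear columns: {bad}")


def build_second_stage_design(
    table: pd.DataFrame,
    scope: str = "combined",
    modifier: str | None = None,
    degree: int = 1,
    city: str | None = None,
    cities_order: list[str] | None = None,
) -> pd.DataFrame:
    """Build the ZCTA-level design matrix X for the meta-regression.

    Parameters
    ----------
    table : DataFrame indexed by ZCTA with a ``city`` column and SES columns
        (continuous indicators and/or boolean flags).
    scope : ``"combined"`` (all cities pooled) or ``"city"``
    modifier : None, or the name of a flag / continuous SES column
    degree : polynomial degree for a continuous modifier (1, 2 or 3)
    city : required when scope is ``"city"``
    """
    if scope not in ("combined", "city"):
        raise Stage2Error("scope must be 'combined' or 'city'")
    if degree not in (1, 2, 3):
        raise Stage2Error("degree must be 1, 2 or 3")
    if scope == "city":
        if city is None:
            raise Stage2Error("city must be given for a city-specific design")
        table = table[table["city"] == city]
        if table.empty:
            raise Stage2Error(f"no ZCTAs for city {city!r}")
    cities = cities_order or list(dict.fromkeys(table["city"]))
    X = pd.DataFrame(index=table.index)
    if scope == "combined" and modifier is None:
        # overall model: one indicator per city, no intercept
        for ct in cities:
            X[f"city_{ct}"] = (table["city"] == ct).astype(float)
    else:
        X["intercept"] = 1.0
        if scope == "combined":
            for ct in cities[1:]:
                X[f"city_{ct}"] = (table["city"] == ct).astype(float)
    if modifier is not None:
        if modifier not in table.columns:
            raise Stage2Error(f"modifier column {modifier!r} not in table")
        col = table[modifier]
        if col.dtype == bool:
            X[modifier] = col.astype(float)
        else:
            vals = col.to_numpy(dtype=float)
            X[modifier] = vals
            for d in range(2, degree + 1):
                X[f"{modifier}^{d}"] = vals**d
    _check_full_rank(X)
    return X


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def _gls_at_tau(beta, V, X, tau):
    """GLS coefficient posterior at fixed tau, plus the tau log-marginal."""
    w = 1.0 / (V + tau**2)
    Xw = X * w[:, None]
    XtWX = X.T @ Xw
    XtWy = Xw.T @ beta
    L = np.linalg.cholesky(XtWX)
    ghat = np.linalg.solve(XtWX, XtWy)
    Sigma = np.linalg.inv(XtWX)
    rss = float(beta @ (w * beta) - ghat @ XtWy)
    logdet = 2.0 * float(np.sum(np.log(np.diag(L))))
    logpost = 0.5 * float(np.sum(np.log(w))) - 0.5 * logdet - 0.5 * rss
    return ghat, Sigma, logpost


@dataclass
class MetaResults:
    """Posterior summaries of a two-level normal meta-regression fit."""

    params: pd.Series          # posterior means of a0 and the g_j
    bse: pd.Series             # posterior SDs
    cov_params: pd.DataFrame   # full posterior covariance (tau-mixture)
    tau_mean: float
    tau_interval: tuple        # 95% interval for tau
    tau_grid: np.ndarray
    tau_weights: np.ndarray
    design: pd.DataFrame
    beta: pd.Series = field(repr=False, default=None)  # type: ignore[assignment]
    var: pd.Series = field(repr=False, default=None)   # type: ignore[assignment]

    @property
    def zvalues(self) -> pd.Series:
        return self.params / self.bse

    def significant(self) -> pd.Series:
        return self.zvalues.abs() > Z_CRIT

    def predict_linear(self, x) -> tuple[float, float]:
        """Posterior mean and SD of the per-ppb linear predictor x' g."""
        x = np.asarray(x, dtype=float)
        if x.shape != (len(self.params),):
            raise Stage2Error(
                f"covariate row of length {x.size} not conformable with "
                f"{len(self.params)} coefficients"
            )
        mean = float(x @ self.params.to_numpy())
        var = float(x @ self.cov_params.to_numpy() @ x)
        return mean, float(np.sqrt(max(var, 0.0)))

    def or_for(self, x, delta_ppb: float = 25.0) -> tuple[float, float, float]:
        """Mean OR and Wald 95% PI for covariate row ``x``, per ``delta_ppb``."""
        mean, sd = self.predict_linear(x)
        lo = np.exp(delta_ppb * (mean - Z_CRIT * sd))
        hi = np.exp(delta_ppb * (mean + Z_CRIT * sd))
        return float(np.exp(delta_ppb * mean)), float(lo), float(hi)

    def theta_summaries(self) -> pd.DataFrame:
        """Shrunken per-ZCTA true-effect summaries E[theta_z], SD[theta_z]."""
        X = self.design.to_numpy(dtype=float)
        beta = self.beta.to_numpy(dtype=float)
        V = self.var.to_numpy(dtype=float)
        means = np.zeros(len(beta))
        seconds = np.zeros(len(beta))
        for tau, w in zip(self.tau_grid, self.tau_weights):
            ghat, Sigma, _ = _gls_at_tau(beta, V, X, tau)
            prior_mean = X @ ghat
            shrink = tau**2 / (tau**2 + V)
            m = shrink * beta + (1 - shrink) * prior_mean
            cond_var = (tau**2 * V) / (tau**2 + V)
            cond_var = cond_var + ((1 - shrink) ** 2) * np.einsum(
                "ij,jk,ik->i", X, Sigma, X
            )
            means += w * m
            seconds += w * (cond_var + m**2)
        sd = np.sqrt(np.maximum(seconds - means**2, 0.0))
        return pd.DataFrame(
            {"theta_mean": means, "theta_sd": sd}, index=self.design.index
        )

    def summary(self) -> str:
        lines = [
            "Two-level normal hierarchical meta-regression",
            f"  ZCTAs pooled: {len(self.design)}   design columns: {list(self.design.columns)}",
            f"  tau posterior mean: {self.tau_mean:.6g}  95% interval: "
            f"({self.tau_interval[0]:.6g}, {self.tau_interval[1]:.6g})",
            "",
            f"  {'coefficient':<22}{'post.mean':>12}{'post.sd':>12}{'z':>9}  sig(|z|>1.96)",
        ]
        for name in self.params.index:
            est, sd = self.params[name], self.bse[name]
            z = est / sd
            lines.append(
                f"  {name:<22}{est:>12.6f}{sd:>12.6f}{z:>9.2f}  {'*' if abs(z) > Z_CRIT else ''}"
            )
        return "\n".join(lines)


class TwoLevelNormalMeta:
    """Model object for the stage-2 hierarchical meta-regression.

    Parameters
    ----------
    beta : Series of stage-1 per-ppb log ORs, indexed by ZCTA
    var : Series of their estimated variances (all > 0), same index
    design : DataFrame from :func:`build_second_stage_design`, same index
    tau_prior : ``"tau"`` (flat on tau, default) or ``"tau2"`` (flat on tau^2)
    tau_max : upper end of the tau integration range; defaults to 10x the
        dispersion (SD) of the stage-1 estimates
    grid_size : points per integration pass (two passes: coarse + refined)
    """

    def __init__(
        self,
        beta: pd.Series,
        var: pd.Series,
        design: pd.DataFrame,
        tau_prior: str = "tau",
        tau_max: float | None = None,
        grid_size: int = 201,
    ):
        beta = pd.Series(beta).astype(float)
        var = pd.Series(var).astype(float).reindex(beta.index)
        design = design.reindex(beta.index)
        if design.isna().any().any() or var.isna().any():
            raise Stage2Error("beta, var and design rows are not aligned")
        if (var <= 0).any():
            raise Stage2Error("all stage-1 variances must be positive")
        if len(beta) < design.shape[1]:
            raise Stage2Error("fewer ZCTAs than design columns")
        if tau_prior not in ("tau", "tau2"):
            raise Stage2Error("tau_prior must be 'tau' or 'tau2'")
        self.beta = beta
        self.var = var
        self.design = design
        self.tau_prior = tau_prior
        self.tau_max = tau_max
        self.grid_size = grid_size

    def _log_prior(self, tau: np.ndarray) -> np.ndarray:
        if self.tau_prior == "tau":
            return np.zeros_like(tau)
        # flat on tau^2 => density 2*tau in tau
        with np.errstate(divide="ignore"):
            return np.where(tau > 0, np.log(2 * tau), -np.inf)

    def _grid_logpost(self, grid: np.ndarray):
        y = self.beta.to_numpy()
        V = self.var.to_numpy()
        X = self.design.to_numpy(dtype=float)
        lps, ghats, Sigmas = [], [], []
        for tau in grid:
            ghat, Sigma, lp = _gls_at_tau(y, V, X, tau)
            ghats.append(ghat)
            Sigmas.append(Sigma)
            lps.append(lp)
        return np.asarray(lps) + self._log_prior(grid), ghats, Sigmas

    def fit(self, tau_grid=None) -> MetaResults:
        if tau_grid is not None:
            grid = np.asarray(tau_grid, dtype=float)
        else:
            tmax = self.tau_max
            if tmax is None:
                disp = float(self.beta.std(ddof=1)) if len(self.beta) > 1 else 0.0
                if not np.isfinite(disp) or disp <= 0:
                    disp = float(np.sqrt(self.var.mean()))
                tmax = 10.0 * disp
            coarse = np.linspace(0.0, tmax, self.grid_size)
            lp, _, _ = self._grid_logpost(coarse)
            finite = np.isfinite(lp)
            keep = finite & (lp > lp[finite].max() - 15.0)
            idx = np.flatnonzero(keep)
            lo = coarse[max(idx.min() - 1, 0)]
            hi = coarse[min(idx.max() + 1, len(coarse) - 1)]
            grid = np.linspace(lo, hi, self.grid_size)
        lp, ghats, Sigmas = self._grid_logpost(grid)
        finite = np.isfinite(lp)
        p = np.zeros_like(lp)
        p[finite] = np.exp(lp[finite] - lp[finite].max())
        if len(grid) > 1:
            dt = np.empty_like(grid)
            dt[1:-1] = (grid[2:] - grid[:-2]) / 2.0
            dt[0] = (grid[1] - grid[0]) / 2.0
            dt[-1] = (grid[-1] - grid[-2]) / 2.0
            w = p * dt
        else:
            w = p.copy()
        w = w / w.sum()

        k = self.design.shape[1]
        mean = np.zeros(k)
        second = np.zeros((k, k))
        for wi, ghat, Sigma in zip(w, ghats, Sigmas):
            mean += wi * ghat
            second += wi * (Sigma + np.outer(ghat, ghat))
        cov = second - np.outer(mean, mean)
        cov = (cov + cov.T) / 2.0
        bse = np.sqrt(np.clip(np.diag(cov), 0.0, None))

        tau_mean = float(np.sum(w * grid))
        if len(grid) > 1:
            cdf = np.cumsum(w)
            tau_lo = float(np.interp(0.025, cdf, grid))
            tau_hi = float(np.interp(0.975, cdf, grid))
        else:
            tau_lo = tau_hi = float(grid[0])

        cols = list(self.design.columns)
        return MetaResults(
            params=pd.Series(mean, index=cols),
            bse=pd.Series(bse, index=cols),
            cov_params=pd.DataFrame(cov, index=cols, columns=cols),
            tau_mean=tau_mean,
            tau_interval=(tau_lo, tau_hi),
            tau_grid=grid,
            tau_weights=w,
            design=self.design,
            beta=self.beta,
            var=self.var,
        )


def fit_two_level_normal(
    beta: pd.Series,
    var: pd.Series,
    design: pd.DataFrame,
    **kwargs,
) -> MetaResults:
    """Functional wrapper around :class:`TwoLevelNormalMeta`."""
    tau_grid = kwargs.pop("tau_grid", None)
    return TwoLevelNormalMeta(beta, var, design, **kwargs).fit(tau_grid=tau_grid)


def wald_significant(estimate: float, posterior_sd: float) -> bool:
    """True iff |estimate / posterior_sd| is strictly greater than 1.96."""
    if posterior_sd <= 0:
        raise Stage2Error("posterior SD must be positive")
    return abs(estimate / posterior_sd) > Z_CRIT


def zcta_mean_or(fit: MetaResults, x_z, delta_ppb: float = 25.0):
    """Mean OR and 95% PI for one ZCTA covariate row, scaled to ``delta_ppb``."""
    return fit.or_for(x_z, delta_ppb=delta_ppb)
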