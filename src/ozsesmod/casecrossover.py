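"""Time-stratified case-crossover estimation by conditional logistic regression.

Each ED visit is its own matched set: the case day is compared with referent
days in the same calendar month and year sharing the case day's day of week,
so time-invariant personal confounders cancel by design.  Within each ZCTA
the per-ppb log odds ratio of the 3-day moving-average ozone is estimated by
maximizing the exact conditional log-likelihood

    l(b) = sum_strata [ x_case . b - log sum_rows exp(x_row . b) ]

with Newton iterations on within-stratum-centered covariates.  The covariate
set controls residual time-varying confounding: season indicators,
day-of-week and holiday indicators, hospital-participation periods, cubic
polynomials of 3-day moving-average maximum temperature and mean dew point,
season x maximum-temperature interactions, and a natural cubic spline on day
of year (5 df).  Covariates constant within every stratum (e.g. day of week,
by construction of the matching) cancel out of the conditional likelihood;
they are retained in the design and dropped only at estimation time.

ZCTAs with fewer than 50 total visits over the study period are excluded
(sparse sets do not support stable conditional-logistic estimation).
"""

from __future__ import annotations

import calendar
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from pandas.tseries.holiday import USFederalHolidayCalendar

from .exposure import ExposureSeries

__all__ = [
    "CovariateSpec",
    "CaseCrossoverStratum",
    "Stage1Error",
    "NonIdentifiableError",
    "build_referent_sets",
    "build_stratum_design",
    "fit_conditional_logistic",
    "exclude_sparse_zctas",
    "run_stage1_city",
    "CaseCrossover",
    "CaseCrossoverResults",
    "natural_cubic_spline_basis",
    "adjusted_day_of_year",
]

SPARSE_VISIT_THRESHOLD = 50


class Stage1Error(RuntimeError):
    pass


class NonIdentifiableError(Stage1Error):
    """The exposure shows no within-stratum variation anywhere."""


# ---------------------------------------------------------------------------
# covariate machinery
# ---------------------------------------------------------------------------

_SEASON_OF_MONTH = {
    12: "DJF", 1: "DJF", 2: "DJF",
    3: "MAM", 4: "MAM", 5: "MAM",
    6: "JJA", 7: "JJA", 8: "JJA",
    9: "SON", 10: "SON", 11: "SON",
}


def adjusted_day_of_year(dates: pd.DatetimeIndex) -> np.ndarray:
    """Day of year on a common 1-366 scale with Feb 29 = 60.

    In non-leap years days from Mar 1 onward are shifted by one so the same
    calendar date maps to the same value every year (no discontinuity at the
    leap boundary).
    """
    doy = dates.dayofyear.to_numpy(dtype=float)
    nonleap = ~dates.is_leap_year
    doy = doy + (nonleap & (doy >= 60)).astype(float)
    return doy


def natural_cubic_spline_basis(x: np.ndarray, knots: np.ndarray) -> np.ndarray:
    """Natural cubic spline basis (linear beyond the boundary knots).

    With K knots the basis has K-1 columns (no intercept column):
    N_1(x) = x and N_{k+1}(x) = d_k(x) - d_{K-1}(x) for k = 1..K-2 where
    d_k(x) = [(x - k_k)_+^3 - (x - k_K)_+^3] / (k_K - k_k).
    """
    x = np.asarray(x, dtype=float)
    knots = np.sort(np.asarray(knots, dtype=float))
    K = len(knots)
    if K < 3:
        raise ValueError("need at least 3 knots")

    def d(k):
        num = np.clip(x - knots[k], 0, None) ** 3 - np.clip(x - knots[K - 1], 0, None) ** 3
        return num / (knots[K - 1] - knots[k])

    cols = [x]
    dlast = d(K - 2)
    for k in range(K - 2):
        cols.append(d(k) - dlast)
    return np.column_stack(cols)


def _spline_knots(doy: np.ndarray, df: int) -> np.ndarray:
    """Boundary knots at min/max, df-1 interior knots at equally spaced quantiles."""
    n_interior = df - 1
    qs = np.linspace(0, 1, n_interior + 2)
    return np.quantile(np.unique(doy), qs)


@dataclass
class CovariateSpec:
    """Covariate structure of the stage-1 conditional logistic model."""

    spline_df: int = 5
    temp_poly_degree: int = 3
    dew_poly_degree: int = 3
    season_temp_interaction: bool = True
    include_season: bool = True
    include_dow: bool = True
    include_holidays: bool = True
    #: optional list of (label, start, end) hospital-participation intervals
    hospital_periods: list | None = None

    def column_names(self) -> list[str]:
        names = ["o3_ma02"]
        if self.include_season:
            names += [f"season_{s}" for s in ("MAM", "JJA", "SON")]
        if self.include_dow:
            names += [f"dow_{d}" for d in range(1, 7)]
        if self.include_holidays:
            names += ["holiday"]
        for lbl, *_ in self.hospital_periods or []:
            names += [f"hosp_{lbl}"]
        names += [f"tmax_ma02_p{q}" for q in range(1, self.temp_poly_degree + 1)]
        names += [f"dew_ma02_p{q}" for q in range(1, self.dew_poly_degree + 1)]
        if self.season_temp_interaction:
            names += [f"season_{s}:tmax_ma02" for s in ("MAM", "JJA", "SON")]
        names += [f"doy_spline_{k}" for k in range(1, self.spline_df + 1)]
        return names


def build_time_covariates(
    dates: pd.DatetimeIndex,
    tmax_ma02: pd.Series | None,
    dew_ma02: pd.Series | None,
    spec: CovariateSpec,
) -> pd.DataFrame:
    """Date-level covariate matrix shared by every ZCTA of a city.

    Values depending on missing meteorology are NaN; rows with NaN are
    removed from strata before fitting.
    """
    n = len(dates)
    cols: dict[str, np.ndarray] = {}
    season = np.array([_SEASON_OF_MONTH[m] for m in dates.month])
    if spec.include_season:
        for s in ("MAM", "JJA", "SON"):
            cols[f"season_{s}"] = (season == s).astype(float)
    if spec.include_dow:
        dow = dates.dayofweek.to_numpy()
        for d in range(1, 7):
            cols[f"dow_{d}"] = (dow == d).astype(float)
    if spec.include_holidays:
        hol = USFederalHolidayCalendar().holidays(start=dates.min(), end=dates.max())
        cols["holiday"] = dates.isin(hol).astype(float)
    for lbl, start, end in spec.hospital_periods or []:
        cols[f"hosp_{lbl}"] = (
            (dates >= pd.Timestamp(start)) & (dates <= pd.Timestamp(end))
        ).astype(float)
    tmax = (
        tmax_ma02.reindex(dates).to_numpy(dtype=float)
        if tmax_ma02 is not None
        else np.zeros(n)
    )
    dew = (
        dew_ma02.reindex(dates).to_numpy(dtype=float)
        if dew_ma02 is not None
        else np.zeros(n)
    )
    for q in range(1, spec.temp_poly_degree + 1):
        cols[f"tmax_ma02_p{q}"] = tmax**q
    for q in range(1, spec.dew_poly_degree + 1):
        cols[f"dew_ma02_p{q}"] = dew**q
    if spec.season_temp_interaction:
        for s in ("MAM", "JJA", "SON"):
            cols[f"season_{s}:tmax_ma02"] = (season == s).astype(float) * tmax
    doy = adjusted_day_of_year(dates)
    basis = natural_cubic_spline_basis(doy, _spline_knots(doy, spec.spline_df))
    for k in range(spec.spline_df):
        cols[f"doy_spline_{k + 1}"] = basis[:, k]
    return pd.DataFrame(cols, index=dates)


# ---------------------------------------------------------------------------
# referent sets and strata
# ---------------------------------------------------------------------------

def build_referent_sets(event_date, study_period) -> list[pd.Timestamp]:
    """All other days in the event's calendar month/year with its day of week."""
    d = pd.Timestamp(event_date)
    start, end = (pd.Timestamp(x) for x in study_period)
    if not (start <= d <= end):
        raise ValueError(f"event date {d.date()} outside study period")
    ndays = calendar.monthrange(d.year, d.month)[1]
    month = pd.date_range(d.replace(day=1), periods=ndays, freq="D")
    same_dow = month[(month.dayofweek == d.dayofweek) & (month != d)]
    return [ts for ts in same_dow if start <= ts <= end]


@dataclass
class CaseCrossoverStratum:
    """One matched set: the case day plus its time-stratified referent days.

    ``X`` holds one covariate row per day (case row at ``case_index``);
    ``weight`` counts identical visits collapsed into this stratum.
    """

    stratum_id: object
    dates: list
    case_index: int
    X: np.ndarray
    columns: list[str]
    weight: float = 1.0

    def __post_init__(self):
        if not (0 <= self.case_index < len(self.dates)):
            raise ValueError("case_index out of range")


def build_stratum_design(
    stratum: dict,
    exposure: ExposureSeries,
    spec: CovariateSpec,
    time_covariates: pd.DataFrame | None = None,
) -> CaseCrossoverStratum | None:
    """Assemble the design rows of one matched set.

    ``stratum`` is a mapping with keys ``zcta``, ``case_date``,
    ``referent_dates`` and optionally ``stratum_id`` / ``weight``.  Rows
    whose exposure or meteorology is missing are removed; if the case row is
    removed or no referent survives, None is returned (stratum dropped).
    """
    zcta = stratum["zcta"]
    case_date = pd.Timestamp(stratum["case_date"])
    dates = [case_date] + [pd.Timestamp(t) for t in stratum["referent_dates"]]
    if time_covariates is None:
        time_covariates = build_time_covariates(
            exposure.dates, exposure.tmax_ma02, exposure.dew_ma02, spec
        )
    o3 = exposure.o3_ma02[zcta]
    rows, kept_dates, case_index = [], [], None
    for t in dates:
        if t not in o3.index or t not in time_covariates.index:
            continue
        xo3 = o3.loc[t]
        cov = time_covariates.loc[t].to_numpy(dtype=float)
        if not np.isfinite(xo3) or not np.all(np.isfinite(cov)):
            continue
        if t == case_date:
            case_index = len(rows)
        kept_dates.append(t)
        rows.append(np.concatenate([[xo3], cov]))
    if case_index is None or len(rows) < 2:
        return None
    return CaseCrossoverStratum(
        stratum_id=stratum.get("stratum_id", (zcta, case_date)),
        dates=kept_dates,
        case_index=case_index,
        X=np.asarray(rows, dtype=float),
        columns=["o3_ma02"] + list(time_covariates.columns),
        weight=float(stratum.get("weight", 1.0)),
    )


# ---------------------------------------------------------------------------
# conditional logistic core
# ---------------------------------------------------------------------------

@dataclass
class ConditionalLogitFit:
    params: pd.Series
    cov_params: pd.DataFrame
    loglik: float
    converged: bool
    n_iter: int
    dropped_columns: list[str]
    n_strata: int


def _fit_core(
    Xrows: np.ndarray,
    sizes: np.ndarray,
    case_offsets: np.ndarray,
    weights: np.ndarray,
    columns: list[str],
    tol: float = 1e-8,
    max_iter: int = 100,
) -> ConditionalLogitFit:
    """Newton maximization of the exact conditional log-likelihood.

    Rows of each stratum are contiguous; ``case_offsets`` are global row
    indices of case rows; ``weights`` count collapsed identical strata.
    Columns are centered within strata (the likelihood is invariant to
    per-stratum shifts); columns that become numerically zero everywhere are
    within-stratum constant and are dropped from estimation.
    """
    sizes = np.asarray(sizes)
    starts = np.concatenate([[0], np.cumsum(sizes)[:-1]])
    rep = np.repeat(np.arange(len(sizes)), sizes)
    means = np.add.reduceat(Xrows, starts, axis=0) / sizes[:, None]
    Xc = Xrows - means[rep]
    span = np.abs(Xc).max(axis=0)
    keep = span > 1e-10
    dropped = [c for c, k in zip(columns, keep) if not k]
    kept_cols = [c for c, k in zip(columns, keep) if k]
    if not kept_cols:
        raise NonIdentifiableError("no covariate varies within any stratum")
    Xk = Xc[:, keep]
    scale = np.abs(Xk).max(axis=0)  # column equilibration for conditioning
    Xk = Xk / scale
    w_s = np.asarray(weights, dtype=float)
    wrep = w_s[rep]
    p = Xk.shape[1]
    b = np.zeros(p)

    def ll_parts(bvec):
        eta = Xk @ bvec
        m = np.maximum.reduceat(eta, starts)
        ex = np.exp(eta - m[rep])
        denom = np.add.reduceat(ex, starts)
        ll = float(np.sum(w_s * (eta[case_offsets] - (np.log(denom) + m))))
        prow = ex / denom[rep]
        return ll, eta, prow

    ll, _, prow = ll_parts(b)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        wrow = prow * wrep
        grad = (w_s[:, None] * Xk[case_offsets]).sum(axis=0) - (wrow[:, None] * Xk).sum(axis=0)
        if np.max(np.abs(grad)) < tol:
            converged = True
            break
        A = Xk * wrow[:, None]
        H1 = Xk.T @ A
        M = np.add.reduceat(A, starts, axis=0) / np.sqrt(w_s)[:, None]
        H = H1 - M.T @ M  # negative Hessian of ll
        try:
            delta = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            delta = np.linalg.lstsq(H, grad, rcond=None)[0]
        step = 1.0
        for _ in range(30):
            ll_new, _, prow_new = ll_parts(b + step * delta)
            if ll_new >= ll - 1e-12:
                break
            step *= 0.5
        b = b + step * delta
        ll, prow = ll_new, prow_new
    else:
        it = max_iter
    # final curvature for the covariance
    wrow = prow * wrep
    A = Xk * wrow[:, None]
    H1 = Xk.T @ A
    M = np.add.reduceat(A, starts, axis=0) / np.sqrt(w_s)[:, None]
    H = H1 - M.T @ M
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(H)
        converged = False
    beta = b / scale
    cov = cov / np.outer(scale, scale)
    return ConditionalLogitFit(
        params=pd.Series(beta, index=kept_cols),
        cov_params=pd.DataFrame(cov, index=kept_cols, columns=kept_cols),
        loglik=ll,
        converged=converged,
        n_iter=it,
        dropped_columns=dropped,
        n_strata=len(sizes),
    )


def conditional_loglik(strata: list[CaseCrossoverStratum], beta: np.ndarray) -> float:
    """Exact conditional log-likelihood at ``beta`` (for diagnostics/oracles)."""
    beta = np.asarray(beta, dtype=float)
    total = 0.0
    for s in strata:
        eta = s.X @ beta
        m = eta.max()
        total += s.weight * (eta[s.case_index] - (np.log(np.exp(eta - m).sum()) + m))
    return float(total)


def fit_conditional_logistic(
    strata: list[CaseCrossoverStratum],
    focus: str | None = None,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> ConditionalLogitFit:
    """Fit the conditional logistic model on explicit matched sets.

    ``focus`` optionally names a column that must remain identifiable
    (raises :class:`NonIdentifiableError` if it is within-stratum constant
    everywhere).
    """
    if not strata:
        raise Stage1Error("no strata to fit")
    columns = strata[0].columns
    rows, sizes, case_offsets, weights = [], [], [], []
    offset = 0
    for s in strata:
        if list(s.columns) != list(columns):
            raise Stage1Error("strata have inconsistent design columns")
        rows.append(s.X)
        sizes.append(s.X.shape[0])
        case_offsets.append(offset + s.case_index)
        weights.append(s.weight)
        offset += s.X.shape[0]
    fit = _fit_core(
        np.vstack(rows),
        np.asarray(sizes),
        np.asarray(case_offsets),
        np.asarray(weights, dtype=float),
        list(columns),
        tol=tol,
        max_iter=max_iter,
    )
    if focus is not None and focus not in fit.params.index:
        raise NonIdentifiableError(
            f"{focus!r} has no within-stratum variation in any matched set"
        )
    return fit


def exclude_sparse_zctas(visit_counts: pd.Series, threshold: int = SPARSE_VISIT_THRESHOLD):
    """Split ZCTAs into (kept, excluded) by total visit count (kept iff >= threshold)."""
    counts = visit_counts.astype(int)
    kept = counts.index[counts >= threshold]
    excluded = counts.index[counts < threshold]
    return list(kept), list(excluded)


# ---------------------------------------------------------------------------
# per-city stage-1 runner
# ---------------------------------------------------------------------------

@dataclass
class CaseCrossoverResults:
    """Per-ZCTA conditional-logistic estimates for one city."""

    estimates: pd.DataFrame  # zcta-indexed: beta_hat, var_hat, n_visits, n_strata, converged
    excluded_zctas: list
    dropped_strata: dict
    city: str | None = None
    spec: CovariateSpec | None = None

    def summary(self) -> str:
        e = self.estimates
        lines = [
            f"Stage 1 case-crossover results{' for ' + self.city if self.city else ''}",
            f"  ZCTAs fitted: {len(e)}  (excluded sparse: {len(self.excluded_zctas)})",
            f"  converged: {int(e['converged'].sum())}/{len(e)}",
            f"  median per-ppb log OR: {e['beta_hat'].median():.5f}",
            f"  median variance: {e['var_hat'].median():.3g}",
        ]
        return "\n".join(lines)


class CaseCrossover:
    """Stage-1 model: per-ZCTA case-crossover conditional logistic regression.

    Parameters
    ----------
    visits : DataFrame with columns ``visit_date``, ``zcta`` (one row/visit)
    exposure : :class:`~ozsesmod.exposure.ExposureSeries` for the city
    spec : covariate structure (defaults to the full control set)
    min_visits : sparse-ZCTA exclusion threshold (total visits)
    """

    def __init__(
        self,
        visits: pd.DataFrame,
        exposure: ExposureSeries,
        spec: CovariateSpec | None = None,
        city: str | None = None,
        min_visits: int = SPARSE_VISIT_THRESHOLD,
    ):
        self.visits = visits
        self.exposure = exposure
        self.spec = spec or CovariateSpec()
        self.city = city
        self.min_visits = min_visits

    def fit(self, tol: float = 1e-8, max_iter: int = 100) -> CaseCrossoverResults:
        visits = self.visits
        expo = self.exposure
        dates = expo.dates
        counts = visits.groupby("zcta").size()
        kept, excluded = exclude_sparse_zctas(counts, self.min_visits)
        if not kept:
            raise Stage1Error(
                "no ZCTA meets the minimum visit count; nothing to estimate"
            )
        time_cov = build_time_covariates(dates, expo.tmax_ma02, expo.dew_ma02, self.spec)
        C = time_cov.to_numpy(dtype=float)
        cov_valid = np.all(np.isfinite(C), axis=1)

        # matched-set structure is a property of the calendar alone
        key = pd.Series(
            list(zip(dates.year, dates.month, dates.dayofweek)), index=dates
        )
        pos_of_date = pd.Series(np.arange(len(dates)), index=dates)
        group_members_all: dict = {}
        for k, grp in pos_of_date.groupby(key.values):
            group_members_all[k] = grp.to_numpy()

        case_dates = pd.DatetimeIndex(pd.to_datetime(visits["visit_date"]))
        date_counts = (
            pd.DataFrame({"zcta": visits["zcta"].to_numpy(), "date": case_dates})
            .groupby(["zcta", "date"])
            .size()
        )

        records = []
        dropped_log: dict = {}
        columns = ["o3_ma02"] + list(time_cov.columns)
        for z in kept:
            o3 = expo.o3_ma02[z].to_numpy(dtype=float)
            valid = cov_valid & np.isfinite(o3)
            zc = date_counts.loc[z]
            members_cache: dict = {}
            strat_rows, sizes, case_offsets, weights = [], [], [], []
            offset = 0
            dropped = 0
            for d, w in zc.items():
                if d not in pos_of_date.index:
                    dropped += 1
                    continue
                t = pos_of_date[d]
                if not valid[t]:
                    dropped += 1
                    continue
                k = (d.year, d.month, d.dayofweek)
                mem = members_cache.get(k)
                if mem is None:
                    mem = group_members_all[k]
                    mem = mem[valid[mem]]
                    members_cache[k] = mem
                if len(mem) < 2:
                    dropped += 1
                    continue
                strat_rows.append(mem)
                sizes.append(len(mem))
                case_offsets.append(offset + int(np.searchsorted(mem, t)))
                weights.append(float(w))
                offset += len(mem)
            dropped_log[z] = dropped
            if not sizes:
                records.append((z, np.nan, np.nan, int(counts[z]), 0, False))
                continue
            row_idx = np.concatenate(strat_rows)
            Xrows = np.column_stack([o3[row_idx], C[row_idx]])
            try:
                fit = _fit_core(
                    Xrows,
                    np.asarray(sizes),
                    np.asarray(case_offsets),
                    np.asarray(weights),
                    columns,
                    tol=tol,
                    max_iter=max_iter,
                )
                if "o3_ma02" not in fit.params.index:
                    raise NonIdentifiableError(z)
                beta = float(fit.params["o3_ma02"])
                var = float(fit.cov_params.loc["o3_ma02", "o3_ma02"])
                records.append((z, beta, var, int(counts[z]), len(sizes), fit.converged))
            except NonIdentifiableError:
                records.append((z, np.nan, np.nan, int(counts[z]), len(sizes), False))
        est = pd.DataFrame(
            records,
            columns=["zcta", "beta_hat", "var_hat", "n_visits", "n_strata", "converged"],
        ).set_index("zcta")
        return CaseCrossoverResults(
            estimates=est,
            excluded_zctas=excluded,
            dropped_strata=dropped_log,
            city=self.city,
            spec=self.spec,
        )


def run_stage1_city(
    visits: pd.DataFrame,
    exposure: ExposureSeries,
    spec: CovariateSpec | None = None,
    city: str | None = None,
    min_visits: int = SPARSE_VISIT_THRESHOLD,
) -> CaseCrossoverResults:
    """Convenience wrapper: fit the stage-1 model for one city."""
    return CaseCrossover(
        visits, exposure, spec=spec, city=city, min_visits=min_visits
    ).fit()
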