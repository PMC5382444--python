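"""Summary surfaces: overall ORs, SES comparison tables, OR-vs-SES curves,
per-ZCTA OR exports for mapping, ED rates per 1000 children, and retention
tables for the sparse-ZCTA exclusion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .hierarchical import MetaResults, Stage2Error

__all__ = [
    "compute_ed_rates",
    "or_curve_table",
    "per_zcta_or_table",
    "overall_or_table",
    "categorical_comparison_table",
    "summarize_exclusions",
    "plot_or_curve",
    "plot_ed_rates",
]


class ReportingError(ValueError):
    pass


def compute_ed_rates(visits: pd.DataFrame, population: pd.DataFrame) -> pd.DataFrame:
    """Annual ED visit rates per 1000 children, averaged over the study period.

    Parameters
    ----------
    visits : line list with ``visit_date`` and ``zcta`` columns, or a
        pre-aggregated table with columns ``zcta``, ``year``, ``visits``
    population : columns ``zcta``, ``year``, ``pop_5_18`` (children 5-18)
    """
    if "visits" in visits.columns:
        counts = visits[["zcta", "year", "visits"]].copy()
    else:
        tmp = visits.copy()
        tmp["year"] = pd.DatetimeIndex(pd.to_datetime(tmp["visit_date"])).year
        counts = tmp.groupby(["zcta", "year"]).size().rename("visits").reset_index()
    merged = population.merge(counts, on=["zcta", "year"], how="left")
    merged["visits"] = merged["visits"].fillna(0).astype(float)
    bad = merged[merged["pop_5_18"] <= 0]
    if len(bad):
        pairs = list(zip(bad["zcta"], bad["year"]))[:10]
        raise ReportingError(f"nonpositive child population for ZCTA-years {pairs}")
    merged["rate_per_1000"] = 1000.0 * merged["visits"] / merged["pop_5_18"]
    period = (
        merged.groupby("zcta")["rate_per_1000"].mean().rename("period_mean_rate")
    )
    return merged.merge(period, on="zcta")


def _quantile(values: np.ndarray, q: float) -> float:
    # linear-interpolation quantile rule (shared with the NDI decile cut)
    return float(np.quantile(np.asarray(values, dtype=float), q))


@dataclass
class ORCurve:
    """OR-vs-SES curve with per-city SES-distribution bounds."""

    table: pd.DataFrame          # city, ses value, OR, PI_lo, PI_hi, within_bounds
    bounds: pd.DataFrame         # per city: 2.5th / 97.5th percentile SES
    ses_name: str


def _city_row(design_cols, city, cities, x_ses):
    """Covariate row for a given city at SES values ``x_ses`` (dict col->val)."""
    row = []
    for col in design_cols:
        if col == "intercept":
            row.append(1.0)
        elif col.startswith("city_"):
            row.append(1.0 if col == f"city_{city}" else 0.0)
        elif col in x_ses:
            row.append(x_ses[col])
        else:
            raise Stage2Error(f"cannot evaluate design column {col!r}")
    return np.asarray(row, dtype=float)


def or_curve_table(
    fit: MetaResults,
    ses_table: pd.DataFrame,
    ses_name: str,
    n_grid: int = 101,
    delta_ppb: float = 25.0,
) -> ORCurve:
    """Evaluate the fitted OR (per ``delta_ppb``) over the SES range.

    The grid spans the pooled SES min-max; each city's 2.5th/97.5th
    percentile bounds of the ZCTA SES distribution are attached and grid
    points outside them flagged (interpretation is reliable only within the
    bounds, where data are not sparse).
    """
    cols = list(fit.design.columns)
    if ses_name not in cols:
        raise Stage2Error(f"fit does not contain modifier {ses_name!r}")
    degree_cols = [c for c in cols if c == ses_name or c.startswith(f"{ses_name}^")]
    vals = ses_table[ses_name].to_numpy(dtype=float)
    grid = np.linspace(vals.min(), vals.max(), n_grid)
    cities = list(dict.fromkeys(ses_table["city"]))
    modeled_cities = [c.removeprefix("city_") for c in cols if c.startswith("city_")]
    if "intercept" in cols:
        curve_cities = cities
    else:
        curve_cities = modeled_cities
    bounds_rows = []
    for ct in curve_cities:
        sub = ses_table.loc[ses_table["city"] == ct, ses_name].to_numpy(dtype=float)
        bounds_rows.append((ct, _quantile(sub, 0.025), _quantile(sub, 0.975)))
    bounds = pd.DataFrame(bounds_rows, columns=["city", "p2_5", "p97_5"]).set_index("city")
    rows = []
    for ct in curve_cities:
        lo_b, hi_b = bounds.loc[ct, "p2_5"], bounds.loc[ct, "p97_5"]
        for v in grid:
            x_ses = {c: v ** (1 if c == ses_name else int(c.split("^")[1])) for c in degree_cols}
            x = _city_row(cols, ct, curve_cities, x_ses)
            orv, lo, hi = fit.or_for(x, delta_ppb=delta_ppb)
            rows.append((ct, v, orv, lo, hi, bool(lo_b <= v <= hi_b)))
    table = pd.DataFrame(
        rows, columns=["city", ses_name, "OR", "PI_lo", "PI_hi", "within_bounds"]
    )
    return ORCurve(table=table, bounds=bounds, ses_name=ses_name)


def per_zcta_or_table(
    fit: MetaResults,
    delta_ppb: float = 25.0,
) -> pd.DataFrame:
    """Estimated mean OR (and PI) per ZCTA from its own design row.

    The export is a plain attribute table keyed on ZCTA, ready to join onto
    user-supplied polygon geometry for mapping.
    """
    rows = []
    X = fit.design
    for z in X.index:
        orv, lo, hi = fit.or_for(X.loc[z].to_numpy(dtype=float), delta_ppb=delta_ppb)
        rows.append((z, orv, lo, hi))
    out = pd.DataFrame(rows, columns=["zcta", "OR", "PI_lo", "PI_hi"]).set_index("zcta")
    return pd.concat([X, out], axis=1)


def overall_or_table(fit: MetaResults, delta_ppb: float = 25.0) -> pd.DataFrame:
    """Per-city overall OR per ``delta_ppb`` from a no-modifier combined fit."""
    cols = list(fit.design.columns)
    rows = []
    for col in cols:
        if not col.startswith("city_"):
            raise Stage2Error("overall table requires the city-indicator design")
        x = np.array([1.0 if c == col else 0.0 for c in cols])
        orv, lo, hi = fit.or_for(x, delta_ppb=delta_ppb)
        rows.append((col.removeprefix("city_"), orv, lo, hi))
    return pd.DataFrame(rows, columns=["city", "OR", "PI_lo", "PI_hi"]).set_index("city")


def categorical_comparison_table(
    fit: MetaResults,
    flag_name: str,
    delta_ppb: float = 25.0,
) -> pd.DataFrame:
    """Low- vs high-SES ORs per city from a combined fit with a flag modifier."""
    cols = list(fit.design.columns)
    if flag_name not in cols:
        raise Stage2Error(f"fit does not contain flag {flag_name!r}")
    cities = [c.removeprefix("city_") for c in cols if c.startswith("city_")]
    all_cities = ["reference"] + cities  # reference = city absorbed by the intercept
    rows = []
    for ct in all_cities:
        for level, lbl in ((1.0, "low_SES"), (0.0, "high_SES")):
            x = []
            for col in cols:
                if col == "intercept":
                    x.append(1.0)
                elif col.startswith("city_"):
                    x.append(1.0 if col == f"city_{ct}" else 0.0)
                elif col == flag_name:
                    x.append(level)
                else:
                    x.append(0.0)
            orv, lo, hi = fit.or_for(np.asarray(x), delta_ppb=delta_ppb)
            rows.append((ct, lbl, orv, lo, hi))
    return pd.DataFrame(rows, columns=["city", "group", "OR", "PI_lo", "PI_hi"])


def summarize_exclusions(
    complete_counts: pd.Series | dict,
    analytical_counts: pd.Series | dict,
) -> pd.DataFrame:
    """Visit retention after the sparse-ZCTA exclusion, per city.

    ``pct_retained`` is rounded to one decimal as conventionally reported;
    ``pct_excluded`` is 100 minus the unrounded retained percentage.
    """
    comp = pd.Series(complete_counts, dtype=float)
    anal = pd.Series(analytical_counts, dtype=float).reindex(comp.index)
    if (anal > comp).any():
        raise ReportingError("analytical counts exceed complete counts")
    retained = 100.0 * anal / comp
    return pd.DataFrame(
        {
            "visits_complete": comp.astype(int),
            "visits_analytical": anal.astype(int),
            "pct_retained": retained.round(1),
            "pct_excluded": 100.0 - retained,
        }
    )


# ---------------------------------------------------------------------------
# plots (matplotlib; saved to files by the CLI)
# ---------------------------------------------------------------------------

def plot_or_curve(curve: ORCurve, ses_table: pd.DataFrame, path=None):
    """OR-vs-SES curve with PI band, SES histogram and percentile bounds."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    cities = list(curve.bounds.index)
    fig, axes = plt.subplots(
        2, len(cities), figsize=(4 * len(cities), 5),
        sharex=True, gridspec_kw={"height_ratios": [3, 1]}, squeeze=False,
    )
    for i, ct in enumerate(cities):
        sub = curve.table[curve.table["city"] == ct]
        ax = axes[0][i]
        ax.fill_between(sub[curve.ses_name], sub["PI_lo"], sub["PI_hi"], alpha=0.3, color="gray")
        ax.plot(sub[curve.ses_name], sub["OR"], color="black")
        ax.axhline(1.0, ls=":", color="gray")
        for b in curve.bounds.loc[ct]:
            ax.axvline(b, ls="--", color="black", lw=0.8)
        ax.set_title(ct)
        ax.set_ylabel("OR per 25 ppb")
        hx = axes[1][i]
        vals = ses_table.loc[ses_table["city"] == ct, curve.ses_name]
        hx.hist(vals, bins=20, color="lightgray", edgecolor="gray")
        hx.set_xlabel(curve.ses_name)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


def plot_ed_rates(rates: pd.DataFrame, ses_table: pd.DataFrame, ses_name: str, path=None):
    """Period-mean ED rates per 1000 children against a SES indicator."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    per_z = rates.groupby("zcta")["period_mean_rate"].first()
    merged = ses_table.join(per_z, how="inner")
    cities = list(dict.fromkeys(merged["city"]))
    fig, axes = plt.subplots(1, len(cities), figsize=(4 * len(cities), 3.5), squeeze=False)
    for i, ct in enumerate(cities):
        sub = merged[merged["city"] == ct]
        ax = axes[0][i]
        ax.plot(sub[ses_name], sub["period_mean_rate"], "+", color="black", alpha=0.6)
        for q in (0.25, 0.5, 0.75):
            ax.axvline(_quantile(sub[ses_name].to_numpy(), q), ls=":", color="gray")
        ax.set_title(ct)
        ax.set_xlabel(ses_name)
        ax.set_ylabel("ED visits per 1000 children / yr")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
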