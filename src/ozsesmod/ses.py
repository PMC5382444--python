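"""Neighborhood socioeconomic status (SES) measures per ZCTA.

Census SES indicators are observed at two waves (a decennial long-form wave
and a later 5-year survey wave).  Yearly values are obtained by straight-line
interpolation between the two anchors and averaged over each city's study
period.  Three measures drive the effect-modification analyses:

* ``pct_lt12`` — % of adults (25+) with less than a 12th-grade education;
* ``pct_poverty`` — % of households below the federal poverty line;
* ``ndi`` — the Neighborhood Deprivation Index, the first principal
  component of eight standardized deprivation indicators, re-standardized
  to mean 0 / SD 1 within each city and oriented so that higher values mean
  more deprivation.

Categorical low-SES designations: "undereducated area" (pct_lt12 >= 25),
"poverty area" (pct_poverty >= 20), and NDI above its 90th percentile
(strictly above, linear-interpolation quantile).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "NDI_INDICATORS",
    "SesError",
    "interpolate_ses_yearly",
    "average_over_period",
    "compute_ndi",
    "classify_ses_categories",
    "build_ses_table",
]

#: The eight deprivation indicators entering the NDI, all on a 0-100 % scale.
NDI_INDICATORS = [
    "pct_low_income",        # households with income < $30,000
    "pct_males_not_mgmt",    # males not in management/professional occupations
    "pct_lt12",              # adults 25+ with < 12th grade education
    "pct_poverty",           # households below the federal poverty line
    "pct_female_headed",     # female-headed households
    "pct_crowding",          # households with > 1 person per room
    "pct_public_assistance", # households on public assistance
    "pct_unemployed",        # unemployed civilian labor force
]

#: Default anchor years: decennial wave at 2000, 5-year survey wave (2007-2011)
#: at its midpoint 2009.
DEFAULT_ANCHORS = (2000, 2009)


class SesError(ValueError):
    pass


def interpolate_ses_yearly(wave1_value, wave2_value, anchor_years, target_year):
    """Straight-line value at ``target_year`` between two anchor observations.

    Extrapolation beyond the anchors is permitted (study periods may extend
    slightly past an anchor year).
    """
    y1, y2 = anchor_years
    if y1 == y2:
        raise SesError("anchor years must be distinct")
    frac = (np.asarray(target_year, dtype=float) - y1) / (y2 - y1)
    return np.asarray(wave1_value) + frac * (np.asarray(wave2_value) - np.asarray(wave1_value))


def average_over_period(yearly_values: dict | pd.Series, period: tuple[int, int]):
    """Arithmetic mean of one value per calendar year across a study period."""
    start, end = period
    years = range(start, end + 1)
    vals = []
    for y in years:
        if y not in yearly_values:
            raise SesError(f"missing SES value for year {y}")
        vals.append(yearly_values[y])
    return float(np.mean(vals))


def _period_mean(wave1, wave2, anchors, period):
    # linear interpolation then averaging == interpolation at the mean year
    start, end = period
    years = np.arange(start, end + 1, dtype=float)
    return interpolate_ses_yearly(wave1, wave2, anchors, years.mean())


def compute_ndi(
    indicators: pd.DataFrame,
    city: pd.Series,
    orient_by: str = "pct_poverty",
) -> pd.Series:
    """Neighborhood Deprivation Index via per-city principal components.

    Within each city the eight indicators are standardized, the first
    principal component of their correlation matrix is extracted, and the
    component scores are re-standardized to mean 0 / SD 1.  The sign is
    chosen so the score correlates positively with ``orient_by`` (higher =
    more deprived).

    Parameters
    ----------
    indicators : DataFrame (ZCTA x 8) with the :data:`NDI_INDICATORS` columns
    city : Series aligned with ``indicators`` giving each ZCTA's city
    """
    missing = [c for c in NDI_INDICATORS if c not in indicators.columns]
    if missing:
        raise SesError(f"missing NDI indicator columns: {missing}")
    if indicators[NDI_INDICATORS].isna().any().any():
        raise SesError("NDI indicators contain missing values")
    out = pd.Series(np.nan, index=indicators.index, name="ndi")
    for ct, idx in indicators.groupby(city).groups.items():
        block = indicators.loc[idx, NDI_INDICATORS].to_numpy(dtype=float)
        if block.shape[0] < 9:
            raise SesError(f"city {ct!r} has fewer than 9 ZCTAs; NDI not identifiable")
        sd = block.std(axis=0, ddof=1)
        tiny = sd <= 1e-10 * np.maximum(1.0, np.abs(block).max(axis=0))
        if np.any(tiny):
            const = [NDI_INDICATORS[i] for i in np.flatnonzero(tiny)]
            raise SesError(f"zero-variance indicator(s) in city {ct!r}: {const}")
        z = (block - block.mean(axis=0)) / sd
        corr = np.corrcoef(z, rowvar=False)
        evals, evecs = np.linalg.eigh(corr)
        pc1 = evecs[:, np.argmax(evals)]
        scores = z @ pc1
        scores = (scores - scores.mean()) / scores.std(ddof=1)
        ref = indicators.loc[idx, orient_by].to_numpy(dtype=float)
        if np.corrcoef(scores, ref)[0, 1] < 0:
            scores = -scores
        out.loc[idx] = scores
    return out


def classify_ses_categories(
    ses: pd.DataFrame,
    ndi_percentile_scope: str = "pooled",
) -> pd.DataFrame:
    """Categorical low-SES designations from a SES table.

    * ``undereducated``: pct_lt12 >= 25 (threshold inclusive)
    * ``poverty_area``: pct_poverty >= 20 (threshold inclusive)
    * ``ndi_top_decile``: ndi strictly above the 90th percentile
      (linear-interpolation quantile), computed over the pooled table or
      within each city according to ``ndi_percentile_scope``.
    """
    flags = pd.DataFrame(index=ses.index)
    flags["undereducated"] = ses["pct_lt12"] >= 25.0
    flags["poverty_area"] = ses["pct_poverty"] >= 20.0
    if ndi_percentile_scope == "pooled":
        cut = float(np.quantile(ses["ndi"].to_numpy(), 0.9))
        flags["ndi_top_decile"] = ses["ndi"] > cut
    elif ndi_percentile_scope == "city":
        flags["ndi_top_decile"] = False
        for ct, idx in ses.groupby("city").groups.items():
            cut = float(np.quantile(ses.loc[idx, "ndi"].to_numpy(), 0.9))
            flags.loc[idx, "ndi_top_decile"] = ses.loc[idx, "ndi"] > cut
    else:
        raise SesError("ndi_percentile_scope must be 'pooled' or 'city'")
    return flags


def build_ses_table(
    raw: pd.DataFrame,
    study_periods: dict[str, tuple],
    anchors: tuple[int, int] = DEFAULT_ANCHORS,
    ndi_percentile_scope: str = "pooled",
) -> pd.DataFrame:
    """Period-averaged SES table with NDI and categorical flags.

    Parameters
    ----------
    raw : long DataFrame with columns ``zcta``, ``city``, ``wave`` (1 or 2)
        and the eight :data:`NDI_INDICATORS`.
    study_periods : mapping city -> (start, end); either calendar years or
        timestamps (from which years are taken).
    """
    for col in ("zcta", "city", "wave"):
        if col not in raw.columns:
            raise SesError(f"raw SES table lacks column {col!r}")
    w1 = raw[raw["wave"] == 1].set_index("zcta")
    w2 = raw[raw["wave"] == 2].set_index("zcta")
    if not w1.index.sort_values().equals(w2.index.sort_values()):
        raise SesError("wave 1 and wave 2 cover different ZCTAs")
    w2 = w2.reindex(w1.index)
    table = pd.DataFrame({"city": w1["city"]}, index=w1.index)
    for ct in table["city"].unique():
        period = study_periods[ct]
        years = tuple(
            p if isinstance(p, int) else pd.Timestamp(p).year for p in period
        )
        idx = table.index[table["city"] == ct]
        for col in NDI_INDICATORS:
            table.loc[idx, col] = _period_mean(
                w1.loc[idx, col].to_numpy(dtype=float),
                w2.loc[idx, col].to_numpy(dtype=float),
                anchors,
                years,
            )
    table["ndi"] = compute_ndi(table[NDI_INDICATORS], table["city"])
    flags = classify_ses_categories(table, ndi_percentile_scope=ndi_percentile_scope)
    return pd.concat([table, flags], axis=1)
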