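"""End-to-end convenience: run both stages on a (synthetic or real) study."""

from __future__ import annotations

import pandas as pd

from .casecrossover import CovariateSpec, run_stage1_city
from .exposure import build_exposure_series
from .hierarchical import MetaResults, TwoLevelNormalMeta, build_second_stage_design
from .ses import build_ses_table
from .simulate import SimulationConfig, StudyData, generate_study

__all__ = ["stage1_all_cities", "run_two_stage", "permute_exposure", "stage1_permuted_null"]


def stage1_all_cities(
    study: StudyData,
    cities,
    spec: CovariateSpec | None = None,
    min_visits: int = 50,
) -> pd.DataFrame:
    """Stage-1 estimates for every city of a study, concatenated."""
    frames = []
    for city in cities:
        field = study.exposure_grid[study.exposure_grid["cell"].str.startswith(city)]
        ov = study.overlap[study.overlap["cell"].str.startswith(city)]
        met = study.met[study.met["city"] == city]
        expo = build_exposure_series(field, ov, met)
        res = run_stage1_city(
            study.visits[study.visits["city"] == city],
            expo,
            spec=spec,
            city=city,
            min_visits=min_visits,
        )
        est = res.estimates.copy()
        est["city"] = city
        frames.append(est)
    return pd.concat(frames)


def permute_exposure(expo, rng):
    """Break the exposure-outcome link by shuffling each ZCTA's daily ozone.

    Each ZCTA's daily series is independently permuted across dates (moving
    averages are recomputed), giving a sharp null for type-I-error checks
    while preserving the marginal exposure distribution.
    """
    from .exposure import ExposureSeries, moving_average_lag02

    o3 = expo.o3.copy()
    for z in o3.columns:
        o3[z] = rng.permutation(o3[z].to_numpy())
    return ExposureSeries(
        o3=o3,
        o3_ma02=moving_average_lag02(o3),
        tmax_ma02=expo.tmax_ma02,
        dew_ma02=expo.dew_ma02,
    )


def stage1_permuted_null(study: StudyData, cities, rng, min_visits: int = 50) -> pd.DataFrame:
    """Stage-1 estimates with per-ZCTA permuted exposure (null data)."""
    frames = []
    for city in cities:
        field = study.exposure_grid[study.exposure_grid["cell"].str.startswith(city)]
        ov = study.overlap[study.overlap["cell"].str.startswith(city)]
        met = study.met[study.met["city"] == city]
        expo = permute_exposure(build_exposure_series(field, ov, met), rng)
        res = run_stage1_city(
            study.visits[study.visits["city"] == city],
            expo,
            city=city,
            min_visits=min_visits,
        )
        est = res.estimates.copy()
        est["city"] = city
        frames.append(est)
    return pd.concat(frames)


def run_two_stage(
    config: SimulationConfig,
    modifier: str | None = "pct_poverty",
    degree: int = 1,
    scope: str = "combined",
    study: StudyData | None = None,
) -> tuple[MetaResults, pd.DataFrame, pd.DataFrame]:
    """Generate (or reuse) a study and run stage 1 + stage 2.

    Returns the meta-regression fit, the stage-1 estimate table and the SES
    table (indexed by the pooled ZCTAs).
    """
    if study is None:
        study = generate_study(config)
    est = stage1_all_cities(study, config.cities)
    est = est[est["converged"] & est["var_hat"].notna()]
    ses = build_ses_table(study.ses_raw, config.study_periods)
    table = ses.loc[est.index]
    design = build_second_stage_design(
        table, scope=scope, modifier=modifier, degree=degree,
        cities_order=list(config.cities),
    )
    fit = TwoLevelNormalMeta(est["beta_hat"], est["var_hat"], design).fit()
    return fit, est, table
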