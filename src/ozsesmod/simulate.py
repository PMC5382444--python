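"""Synthetic three-city study generator with recorded ground truth.

Real pediatric emergency-department (ED) line lists are confidential
hospital records, so every downstream stage of the pipeline is exercised on
synthetic data generated here.  The generator emulates the study design:

* three cities with their own multi-year daily study periods and a few
  hundred ZCTAs each;
* daily gridded ambient 8-h max ozone on a small rectangular lattice per
  city, with a shared seasonal cycle, so that ZCTA exposure must be
  area-weighted exactly as with a real fused field;
* city-level daily maximum temperature and mean dew point;
* two-wave census-style SES tables (eight deprivation indicators, waves
  correlated ~0.9 to mimic decadal stability);
* per-ZCTA true per-ppb log odds ratios drawn from the second-level model
  theta_z = alpha0 + sum_j gamma_j X_zj + N(0, tau^2), where X_zj are the
  period-averaged SES values the analysis itself would compute;
* daily visit counts that are Poisson with log-rate
  baseline_z + confounder(t) + theta_z * ozone_ma02(t, z), realized as an
  individual-visit line list (independent visits, so Poisson daily counts
  are equivalent to modelling individuals).

The seasonal confounder enters both the ozone mean and the visit log-rate,
so stage-1 covariate control is genuinely needed.  Every generating
parameter is recorded in a :class:`TruthRecord` for recovery tests.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .exposure import build_exposure_series, moving_average_lag02
from .ses import NDI_INDICATORS, DEFAULT_ANCHORS, build_ses_table

__all__ = [
    "SimulationConfig",
    "TruthRecord",
    "StudyData",
    "ConfigError",
    "AlignmentError",
    "generate_study",
    "simulate_daily_counts",
]


class ConfigError(ValueError):
    pass


class AlignmentError(ValueError):
    pass


# mean, SD and loading on the latent deprivation factor for each indicator
_INDICATOR_MODEL = {
    "pct_low_income": (25.0, 10.0, 0.85),
    "pct_males_not_mgmt": (60.0, 10.0, 0.6),
    "pct_lt12": (16.0, 8.0, 0.8),
    "pct_poverty": (13.0, 8.0, 0.85),
    "pct_female_headed": (15.0, 8.0, 0.7),
    "pct_crowding": (5.0, 4.0, 0.6),
    "pct_public_assistance": (3.0, 3.0, 0.7),
    "pct_unemployed": (7.0, 4.0, 0.75),
}


@dataclass
class SimulationConfig:
    """Generating parameters for a synthetic multi-city study.

    Defaults reproduce the published study's layout: Atlanta 2002-2008
    (191 ZCTAs), Dallas 2006-2008 (253), St. Louis 2002-2007 (256); a true
    average association of log(1.08)/25 per ppb (OR 1.08 per 25 ppb); a
    small poverty modifier; and between-ZCTA SD tau = 0.001.
    """

    cities: tuple = ("Atlanta", "Dallas", "StLouis")
    zctas_per_city: tuple = (191, 253, 256)
    study_periods: dict = field(
        default_factory=lambda: {
            "Atlanta": ("2002-01-01", "2008-12-31"),
            "Dallas": ("2006-01-01", "2008-12-31"),
            "StLouis": ("2002-01-01", "2007-12-31"),
        }
    )
    alpha0: float = math.log(1.08) / 25.0  # per-ppb log OR
    gamma: dict = field(default_factory=lambda: {"pct_poverty": 0.0002})
    tau: float = 0.001
    baseline_rate_range: tuple = (0.02, 1.5)  # expected visits/day, log-uniform
    ozone_mean: dict = field(
        default_factory=lambda: {"Atlanta": 42.2, "Dallas": 42.0, "StLouis": 40.0}
    )
    ozone_seasonal_amplitude: float = 12.0  # ppb, summer peak
    ozone_daily_sd: float = 6.0            # citywide day-to-day noise, ppb
    ozone_cell_sd: float = 2.0             # cell-level noise, ppb
    tmax_mean: dict = field(
        default_factory=lambda: {"Atlanta": 63.1, "Dallas": 68.8, "StLouis": 57.9}
    )
    tmax_seasonal_amplitude: float = 18.0  # F
    confounding_strength: float = 0.3      # seasonal amplitude on the log-rate
    seed: int = 0

    def validate(self) -> None:
        if not self.cities:
            raise ConfigError("city list is empty")
        if len(self.zctas_per_city) != len(self.cities):
            raise ConfigError("zctas_per_city must match cities")
        if self.tau < 0:
            raise ConfigError("tau must be nonnegative")
        lo, hi = self.baseline_rate_range
        if not (0 < lo <= hi):
            raise ConfigError("baseline rates must be positive and ordered")
        for ct in self.cities:
            start, end = (pd.Timestamp(d) for d in self.study_periods[ct])
            if end <= start:
                raise ConfigError(f"study period for {ct} is not well-ordered")


@dataclass
class TruthRecord:
    """Ground truth of one generated study, for recovery tests."""

    alpha0: float
    gamma: dict
    tau: float
    theta_z: dict          # zcta -> true per-ppb log OR
    baseline_log_rate: dict
    ses_values: dict       # zcta -> {modifier: period-averaged value used}
    city_of: dict          # zcta -> city

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path) -> "TruthRecord":
        return cls(**json.loads(Path(path).read_text()))

    def theta_series(self) -> pd.Series:
        return pd.Series(self.theta_z, name="theta").sort_index()


@dataclass
class StudyData:
    """All tables of a generated study, in the pipeline's input schemas."""

    visits: pd.DataFrame        # visit_date, zcta, city (one row per visit)
    exposure_grid: pd.DataFrame  # date, cell, value (daily 8-h max ozone, ppb)
    met: pd.DataFrame           # date, city, tmax, dewpoint
    ses_raw: pd.DataFrame       # zcta, city, wave, 8 indicators
    overlap: pd.DataFrame       # zcta, cell, area
    population: pd.DataFrame    # zcta, year, pop_5_18
    truth: TruthRecord
    diagnosis: str = "respiratory (ICD-9 460-486, 493, 786.07 analog)"
    age_band: str = "5-18"

    def write(self, outdir) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.visits.to_csv(out / "visits.csv", index=False)
        self.exposure_grid.to_csv(out / "exposure_grid.csv", index=False)
        self.met.to_csv(out / "meteorology.csv", index=False)
        self.ses_raw.to_csv(out / "ses_raw.csv", index=False)
        self.overlap.to_csv(out / "overlap.csv", index=False)
        self.population.to_csv(out / "population.csv", index=False)
        self.truth.to_json(out / "truth.json")


def _annual_cycle(dates: pd.DatetimeIndex, peak_doy: float = 196.0) -> np.ndarray:
    """Smooth annual cycle in [-1, 1] peaking in mid-July."""
    doy = dates.dayofyear.to_numpy(dtype=float)
    return np.cos(2.0 * np.pi * (doy - peak_doy) / 365.25)


def simulate_daily_counts(
    theta_z: float,
    exposure: pd.Series,
    baseline_log_rate: pd.Series,
    rng: np.random.Generator,
) -> pd.Series:
    """Poisson daily counts with expectation exp(baseline_t + theta_z * ozone_t).

    A baseline of -inf is a sentinel for rate zero and yields count 0.
    Exposure and baseline series must share an identical date index.
    """
    if not exposure.index.equals(baseline_log_rate.index):
        raise AlignmentError("exposure and baseline series are not date-aligned")
    log_mu = baseline_log_rate.to_numpy(dtype=float) + theta_z * exposure.to_numpy(dtype=float)
    mu = np.exp(log_mu)
    mu[~np.isfinite(log_mu)] = 0.0
    return pd.Series(rng.poisson(mu), index=exposure.index, name="count")


def _city_grid(n_zcta: int, rng: np.random.Generator, prefix: str):
    """A small rectangular lattice and ZCTA overlap fractions over <=4 cells."""
    side = max(2, int(math.ceil(math.sqrt(n_zcta / 3.0))))
    cells = [f"{prefix}_c{i}_{j}" for i in range(side) for j in range(side)]
    rows = []
    for z in range(n_zcta):
        i = int(rng.integers(side))
        j = int(rng.integers(side))
        neigh = [(i, j)]
        for di, dj in ((1, 0), (0, 1), (1, 1)):
            if i + di < side and j + dj < side:
                neigh.append((i + di, j + dj))
        k = int(rng.integers(1, len(neigh) + 1))
        chosen = neigh[:k]
        fracs = rng.dirichlet(np.ones(len(chosen)))
        for (ci, cj), f in zip(chosen, fracs):
            rows.append((z, f"{prefix}_c{ci}_{cj}", float(f)))
    return cells, rows


def generate_study(config: SimulationConfig) -> StudyData:
    """Generate one full synthetic study (all inputs plus ground truth)."""
    config.validate()
    rng = np.random.default_rng(config.seed)

    visits_rows = []
    grid_rows = []
    met_rows = []
    ses_rows = []
    overlap_rows = []
    pop_rows = []
    theta_z: dict = {}
    base_rate: dict = {}
    ses_used: dict = {}
    city_of: dict = {}

    for ci, city in enumerate(config.cities):
        n_z = int(config.zctas_per_city[ci])
        start, end = (pd.Timestamp(d) for d in config.study_periods[city])
        dates = pd.date_range(start, end, freq="D")
        zctas = [f"{city[:2].upper()}{z:04d}" for z in range(n_z)]

        # --- exposure grid and overlap table -------------------------------
        cells, ov = _city_grid(n_z, rng, city)
        for zi, cell, frac in ov:
            overlap_rows.append((zctas[zi], cell, frac))
        cyc = _annual_cycle(dates)
        city_noise = rng.normal(0.0, config.ozone_daily_sd, len(dates))
        base_o3 = (
            config.ozone_mean.get(city, 42.0)
            + config.ozone_seasonal_amplitude * cyc
            + city_noise
        )
        cell_field = (
            base_o3[:, None]
            + rng.normal(0.0, config.ozone_cell_sd, (len(dates), len(cells)))
        )
        np.clip(cell_field, 0.0, None, out=cell_field)
        gdf = pd.DataFrame(cell_field, index=dates, columns=cells)
        grid_rows.append(
            gdf.stack().rename("value").reset_index().set_axis(
                ["date", "cell", "value"], axis=1
            )
        )

        # --- meteorology (one station per city) ----------------------------
        tmax = (
            config.tmax_mean.get(city, 63.0)
            + config.tmax_seasonal_amplitude * cyc
            + rng.normal(0.0, 4.0, len(dates))
        )
        dew = tmax - 12.0 + rng.normal(0.0, 3.0, len(dates))
        met_rows.append(
            pd.DataFrame({"date": dates, "city": city, "tmax": tmax, "dewpoint": dew})
        )

        # --- two-wave SES tables -------------------------------------------
        latent = rng.normal(0.0, 1.0, n_z)
        drift = 0.9 * latent + math.sqrt(1 - 0.9**2) * rng.normal(0.0, 1.0, n_z)
        for wave, fac in ((1, latent), (2, drift)):
            tab = {"zcta": zctas, "city": city, "wave": wave}
            for ind in NDI_INDICATORS:
                mu, sd, load = _INDICATOR_MODEL[ind]
                vals = mu + sd * (
                    load * fac + math.sqrt(1 - load**2) * rng.normal(0.0, 1.0, n_z)
                )
                tab[ind] = np.clip(vals, 0.0, 100.0)
            ses_rows.append(pd.DataFrame(tab))

        # --- child population denominators ---------------------------------
        pops = np.exp(rng.normal(np.log(3000.0), 0.6, n_z))
        for z, p in zip(zctas, pops):
            for year in range(start.year, end.year + 1):
                pop_rows.append((z, year, int(round(p * (1 + 0.01 * (year - start.year))))))

        for z in zctas:
            city_of[z] = city

    overlap = pd.DataFrame(overlap_rows, columns=["zcta", "cell", "area"])
    exposure_grid = pd.concat(grid_rows, ignore_index=True)
    met = pd.concat(met_rows, ignore_index=True)
    ses_raw = pd.concat(ses_rows, ignore_index=True)
    population = pd.DataFrame(pop_rows, columns=["zcta", "year", "pop_5_18"])

    # --- second-level truth: theta_z from the period-averaged SES ----------
    ses_table = build_ses_table(ses_raw, config.study_periods, DEFAULT_ANCHORS)
    for z in ses_table.index:
        lin = config.alpha0
        used = {}
        for name, g in config.gamma.items():
            x = float(ses_table.loc[z, name])
            lin += g * x
            used[name] = x
        theta_z[z] = lin + (rng.normal(0.0, config.tau) if config.tau > 0 else 0.0)
        ses_used[z] = used

    # --- daily counts and the visit line list ------------------------------
    lo, hi = config.baseline_rate_range
    for ci, city in enumerate(config.cities):
        zctas = [z for z, ct in city_of.items() if ct == city]
        ov_city = overlap[overlap["zcta"].isin(zctas)]
        grid_city = exposure_grid[exposure_grid["cell"].str.startswith(city)]
        expo = build_exposure_series(grid_city, ov_city)
        ma = expo.o3_ma02
        for z in zctas:
            rate = math.exp(rng.uniform(math.log(lo), math.log(hi)))
            base_rate[z] = math.log(rate)
            series = ma[z]
            baseline = pd.Series(base_rate[z], index=series.index)
            baseline = baseline + config.confounding_strength * _annual_cycle(
                pd.DatetimeIndex(series.index)
            )
            baseline[series.isna()] = -np.inf  # no exposure window -> no cases
            counts = simulate_daily_counts(theta_z[z], series.fillna(0.0), baseline, rng)
            nz = counts[counts > 0]
            for d, c in nz.items():
                visits_rows.extend([(d.date().isoformat(), z, city)] * int(c))

    visits = pd.DataFrame(visits_rows, columns=["visit_date", "zcta", "city"])
    truth = TruthRecord(
        alpha0=config.alpha0,
        gamma=dict(config.gamma),
        tau=config.tau,
        theta_z=theta_z,
        baseline_log_rate=base_rate,
        ses_values=ses_used,
        city_of=city_of,
    )
    return StudyData(
        visits=visits,
        exposure_grid=exposure_grid,
        met=met,
        ses_raw=ses_raw,
        overlap=overlap,
        population=population,
        truth=truth,
    )
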