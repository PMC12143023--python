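"""Synthetic study world with known ground truth.

The real study consumed confidential hospitalization records and several
gridded environmental products.  This module generates structurally
equivalent stand-ins so that every downstream stage — exposure construction,
cohort building, conditional-logistic interaction inference — is testable
end-to-end without any download:

* daily gridded maximum temperature with a mid-summer seasonal peak,
* daily gridded PM2.5 with episodic plume-driven spikes and a binary
  plume mask concentrated in the May–November fire season,
* a static gridded population surface and a cell→ZCTA crosswalk
  (contiguous rectangular ZCTA blocks; no real shapefiles),
* hospitalization case series whose within-stratum admission-day
  probabilities follow exactly the conditional-logistic model
  ``exp(bH*xHEAT + bS*xSMOKE + bHS*xHEAT*xSMOKE)`` evaluated at
  configurable truth lags.

Because cases are generated conditional on the same day-of-week-within-
month-year strata the analysis uses, parameter recovery is exact in
expectation.

Everything is deterministic given ``SimulationConfig.seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd

__all__ = [
    "ConfigurationError",
    "SimulationTruth",
    "SimulationConfig",
    "Environment",
    "generate_environment",
    "simulate_cases",
    "simulate_strata",
]


class ConfigurationError(ValueError):
    """Invalid simulation configuration."""


@dataclass(frozen=True)
class SimulationTruth:
    """The data-generating coefficients of the conditional-logistic model.

    ``beta_H`` is the log-odds increment per extreme-heat day, ``beta_S``
    per 1 ug/m3 of wildfire-influenced PM2.5, ``beta_HS`` the interaction
    per (heat day x 1 ug/m3).  ``heat_lag``/``smoke_lag`` are the lag days
    (0–3) at which the true effects act.
    """

    beta_H: float = 0.3
    beta_S: float = 0.05
    beta_HS: float = 0.08
    heat_lag: int = 0
    smoke_lag: int = 3

    def __post_init__(self):
        for name in ("beta_H", "beta_S", "beta_HS"):
            if not np.isfinite(getattr(self, name)):
                raise ConfigurationError(f"{name} must be finite")
        for name in ("heat_lag", "smoke_lag"):
            if getattr(self, name) not in (0, 1, 2, 3):
                raise ConfigurationError(f"{name} must be in 0..3")


# Individual-level demographic defaults follow the printed all-natural-cause
# case mix (sex 42.4/57.6; age 36.0/23.8/40.2; language 85.2/10.5/4.3;
# race/ethnicity with the small groups collapsed into "Other").
DEFAULT_DEMOGRAPHICS: dict[str, dict[str, float]] = {
    "sex": {"Male": 0.424, "Female": 0.576},
    "age_group": {"18-49": 0.360, "50-64": 0.238, "65+": 0.402},
    "language": {"English": 0.852, "Spanish": 0.105, "Other": 0.043},
    "race_ethnicity": {
        "White": 0.498,
        "Black": 0.092,
        "Hispanic": 0.277,
        "Asian": 0.087,
        "Other": 0.046,
    },
}

# ZCTA-level community-disadvantage prevalences (share of cases residing in
# high-poverty / low-education / majority-rural ZCTAs).
DEFAULT_COMMUNITY_RATES: dict[str, float] = {
    "high_poverty": 0.188,
    "low_education": 0.318,
    "rural": 0.028,
}

# admission diagnosis mix over outcome groups; "other_natural" draws codes
# outside the cause-specific lists but inside all-natural morbidity
DEFAULT_OUTCOME_MIX: dict[str, float] = {
    "respiratory": 0.25,
    "cardiovascular": 0.25,
    "cerebrovascular": 0.15,
    "renal": 0.15,
    "other_natural": 0.20,
}

# representative category codes per outcome for synthetic diagnoses
_ICD_POOLS: dict[str, dict[int, list[str]]] = {
    "respiratory": {
        10: ["J00", "J06", "J12", "J18", "J21", "J30", "J40", "J45", "J47",
             "J81", "J90", "J94", "J96", "R05", "R09"],
        9: ["460", "466", "471", "477", "480", "486", "491", "493", "496",
            "511", "518", "786"],
    },
    "cardiovascular": {
        10: ["I00", "I10", "I21", "I25", "I30", "I48", "I50", "I5A", "I70"],
        9: ["390", "401", "410", "414", "420", "427", "428", "440", "449"],
    },
    "cerebrovascular": {
        10: ["I60", "I61", "I63", "I65", "I67", "I69"],
        9: ["430", "431", "434", "436", "438"],
    },
    "renal": {
        10: ["N00", "N08", "N10", "N13", "N17", "N18", "N23", "N25", "R30",
             "R34", "R39"],
        9: ["580", "584", "585", "589", "591", "595", "599", "788"],
    },
    "other_natural": {
        10: ["A41", "E11", "F32", "G40", "K52", "K80", "L03", "M54"],
        9: ["038", "250", "296", "345", "558", "574", "682", "724"],
    },
}

_SEASON_PEAK_DOY = 196  # mid-July peak of the Tmax sinusoid


@dataclass(frozen=True)
class SimulationConfig:
    """Stated world of the synthetic study.

    Grid dimensions, the calendar span (at least two full years so monthly
    baselines and percentile thresholds are estimable), climatology and
    plume parameters, the case count, and the ground-truth coefficients.
    """

    n_cells_x: int = 6
    n_cells_y: int = 6
    date_start: str = "2011-01-01"
    date_end: str = "2012-12-31"
    n_zctas: int = 9
    mean_tmax_F: float = 75.0
    seasonal_amplitude_F: float = 20.0
    tmax_noise_sd_F: float = 7.0
    baseline_pm25_mean: float = 8.0  # ug/m3, lognormal background mean
    baseline_pm25_sd: float = 4.0
    plume_rate: float = 6.0  # expected plume events per cell per May-Nov season
    plume_mean_duration_days: float = 3.0
    plume_pm25_boost: float = 20.0  # ug/m3 added under plume
    mean_cell_population: float = 1000.0
    n_cases: int = 10_000
    heat_percentile: int = 95
    icd10_from_year: int = 2016  # coding-system switch; earlier years use ICD-9
    truth: SimulationTruth = field(default_factory=SimulationTruth)
    demographics: dict = field(default_factory=lambda: DEFAULT_DEMOGRAPHICS)
    community_rates: dict = field(default_factory=lambda: DEFAULT_COMMUNITY_RATES)
    outcome_mix: dict = field(default_factory=lambda: DEFAULT_OUTCOME_MIX)
    seed: int = 0

    def __post_init__(self):
        start, end = pd.Timestamp(self.date_start), pd.Timestamp(self.date_end)
        if end + pd.Timedelta(days=1) < start + pd.DateOffset(years=2):
            raise ConfigurationError(
                "date range must span at least 2 full calendar years"
            )
        for name in ("tmax_noise_sd_F", "baseline_pm25_mean", "baseline_pm25_sd",
                     "plume_rate", "plume_pm25_boost", "n_cases"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if self.n_zctas > self.n_cells_x * self.n_cells_y:
            raise ConfigurationError("n_zctas exceeds the number of grid cells")

    @property
    def n_cells(self) -> int:
        return self.n_cells_x * self.n_cells_y

    @property
    def dates(self) -> pd.DatetimeIndex:
        return pd.date_range(self.date_start, self.date_end, freq="D")


class Environment(NamedTuple):
    """All gridded inputs of one synthetic study."""

    tmax: pd.DataFrame  # cell_id, date, value (deg F)
    pm25: pd.DataFrame  # cell_id, date, value (ug/m3)
    plumes: pd.DataFrame  # cell_id, date, plume_present, density_class
    population: pd.DataFrame  # cell_id, value (persons, static)
    crosswalk: pd.DataFrame  # cell_id, zcta_id, population
    zip_to_zcta: dict  # synthetic ZIP -> ZCTA mapping


def _zcta_blocks(config: SimulationConfig) -> np.ndarray:
    """Contiguous ZCTA blocks over the row-major cell index."""
    assignments = np.empty(config.n_cells, dtype=int)
    for z, chunk in enumerate(np.array_split(np.arange(config.n_cells), config.n_zctas)):
        assignments[chunk] = z
    return assignments


def zcta_zip(zcta_id: int) -> str:
    """Synthetic 5-digit ZIP code for a ZCTA."""
    return f"{90000 + int(zcta_id):05d}"


def generate_environment(config: SimulationConfig) -> Environment:
    """Generate the full gridded world for one simulation.

    Tmax is a mid-summer-peaked sinusoid around ``mean_tmax_F`` plus
    Gaussian noise.  PM2.5 is a lognormal background with
    ``plume_pm25_boost`` added on plume days.  Plumes are multi-day runs
    (geometric durations) whose starts fall in May–November, with the
    event count per cell-season Poisson(``plume_rate``).  Deterministic
    given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    dates = config.dates
    n_days, n_cells = len(dates), config.n_cells

    doy = dates.dayofyear.to_numpy()
    seasonal = config.mean_tmax_F + config.seasonal_amplitude_F * np.cos(
        2.0 * np.pi * (doy - _SEASON_PEAK_DOY) / 365.25
    )
    noise = (
        rng.normal(0.0, config.tmax_noise_sd_F, size=(n_cells, n_days))
        if config.tmax_noise_sd_F > 0
        else np.zeros((n_cells, n_days))
    )
    tmax_vals = seasonal[None, :] + noise

    # plume runs: Poisson event counts per cell-season, geometric durations
    plume = np.zeros((n_cells, n_days), dtype=bool)
    years = dates.year.to_numpy()
    months = dates.month.to_numpy()
    for year in np.unique(years):
        season = np.flatnonzero((years == year) & (months >= 5) & (months <= 11))
        if season.size == 0:
            continue
        n_events = rng.poisson(config.plume_rate, size=n_cells)
        for cell in range(n_cells):
            if n_events[cell] == 0:
                continue
            starts = rng.choice(season, size=n_events[cell], replace=True)
            durations = rng.geometric(
                1.0 / max(config.plume_mean_duration_days, 1.0), size=n_events[cell]
            )
            for s, dur in zip(starts, durations):
                plume[cell, s : min(s + dur, n_days)] = True

    if config.baseline_pm25_mean > 0:
        m, s = config.baseline_pm25_mean, config.baseline_pm25_sd
        sigma2 = np.log1p((s / m) ** 2) if s > 0 else 0.0
        mu = np.log(m) - sigma2 / 2.0
        background = rng.lognormal(mu, np.sqrt(sigma2), size=(n_cells, n_days))
    else:
        background = np.zeros((n_cells, n_days))
    pm25_vals = background + config.plume_pm25_boost * plume

    population = rng.poisson(config.mean_cell_population, size=n_cells) + 1

    density = np.full((n_cells, n_days), "none", dtype=object)
    dens_draw = rng.choice(
        ["light", "medium", "heavy"], p=[0.5, 0.3, 0.2], size=(n_cells, n_days)
    )
    density[plume] = dens_draw[plume]

    cell_ids = np.repeat(np.arange(n_cells), n_days)
    date_col = np.tile(dates.to_numpy(), n_cells)
    tmax = pd.DataFrame(
        {"cell_id": cell_ids, "date": date_col, "value": tmax_vals.ravel()}
    )
    pm25 = pd.DataFrame(
        {"cell_id": cell_ids, "date": date_col, "value": pm25_vals.ravel()}
    )
    plumes = pd.DataFrame(
        {
            "cell_id": cell_ids,
            "date": date_col,
            "plume_present": plume.ravel(),
            "density_class": density.ravel(),
        }
    )
    pop_df = pd.DataFrame(
        {"cell_id": np.arange(n_cells), "value": population.astype(float)}
    )
    zcta = _zcta_blocks(config)
    crosswalk = pd.DataFrame(
        {
            "cell_id": np.arange(n_cells),
            "zcta_id": zcta,
            "population": population.astype(float),
        }
    )
    zip_map = {zcta_zip(z): z for z in range(config.n_zctas)}
    return Environment(tmax, pm25, plumes, pop_df, crosswalk, zip_map)


def _draw_categorical(rng, dist: dict[str, float], n: int) -> np.ndarray:
    keys = list(dist.keys())
    p = np.asarray([dist[k] for k in keys], dtype=float)
    p = p / p.sum()
    return rng.choice(keys, p=p, size=n)


def simulate_cases(
    config: SimulationConfig,
    exposure: pd.DataFrame,
    thresholds: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Draw hospitalization records from the conditional-logistic model.

    For each case a ZCTA and a (year, month, day-of-week) stratum are drawn
    uniformly; the admission day is then drawn from the stratum's eligible
    days with probability proportional to
    ``exp(bH*xH + bS*xS + bHS*xH*xS)`` evaluated at the truth lags — exactly
    the process the conditional-logistic analysis assumes.  Eligible days
    start at ``date_start + 3`` so every admission has full lag history.

    ``exposure`` must carry ``zcta_id, date, wf_pm25`` and either a
    ``heat_day`` column or ``thresholds`` to derive one at
    ``config.heat_percentile``.
    """
    from . import exposures as _exp

    if "heat_day" not in exposure.columns:
        if thresholds is None:
            raise ConfigurationError(
                "exposure lacks heat_day and no thresholds were provided"
            )
        exposure = _exp.flag_extreme_heat(
            exposure, thresholds, percentile=config.heat_percentile
        )

    rng = np.random.default_rng(config.seed + 1)  # independent of environment
    dates = config.dates
    date_pos = pd.Series(np.arange(len(dates)), index=dates)

    zctas = np.sort(exposure["zcta_id"].unique())
    z_pos = pd.Series(np.arange(len(zctas)), index=zctas)
    heat = np.full((len(zctas), len(dates)), np.nan)
    smoke = np.full((len(zctas), len(dates)), np.nan)
    rows = z_pos.loc[exposure["zcta_id"]].to_numpy()
    cols = date_pos.loc[pd.DatetimeIndex(exposure["date"])].to_numpy()
    heat[rows, cols] = exposure["heat_day"].to_numpy().astype(float)
    smoke[rows, cols] = exposure["wf_pm25"].to_numpy().astype(float)

    # enumerate time strata (year, month, day of week) with eligible days
    eligible = np.arange(3, len(dates))  # lag history of 3 days required
    key = pd.DataFrame(
        {
            "pos": eligible,
            "year": dates.year.to_numpy()[eligible],
            "month": dates.month.to_numpy()[eligible],
            "dow": dates.dayofweek.to_numpy()[eligible],
        }
    )
    groups = [g["pos"].to_numpy() for _, g in key.groupby(["year", "month", "dow"])]
    n_resampled = sum(1 for g in groups if len(g) < 2)
    groups = [g for g in groups if len(g) >= 2]
    max_m = max(len(g) for g in groups)
    day_mat = np.full((len(groups), max_m), -1)
    for i, g in enumerate(groups):
        day_mat[i, : len(g)] = g
    mask = day_mat >= 0

    t = config.truth
    z_draw = rng.integers(0, len(zctas), size=config.n_cases)
    s_draw = rng.integers(0, len(groups), size=config.n_cases)

    cand = day_mat[s_draw]  # (n_cases, max_m) candidate date positions
    cmask = mask[s_draw]
    safe = np.where(cand >= 0, cand, 3)
    xh = heat[z_draw[:, None], safe - t.heat_lag]
    xs = smoke[z_draw[:, None], safe - t.smoke_lag]
    if np.isnan(xh[cmask]).any() or np.isnan(xs[cmask]).any():
        raise ConfigurationError("exposure series does not cover all ZCTAs/dates")
    eta = t.beta_H * xh + t.beta_S * xs + t.beta_HS * xh * xs
    gumbel = rng.gumbel(size=eta.shape)
    score = np.where(cmask, eta + gumbel, -np.inf)
    chosen = np.take_along_axis(
        cand, score.argmax(axis=1)[:, None], axis=1
    ).ravel()

    admission = dates[chosen]
    zcta_ids = zctas[z_draw]

    flags = {
        name: rng.random(len(zctas)) < rate
        for name, rate in config.community_rates.items()
    }
    outcome = _draw_categorical(rng, config.outcome_mix, config.n_cases)
    icd_version = np.where(
        admission.year >= config.icd10_from_year, 10, 9
    )
    codes = np.empty(config.n_cases, dtype=object)
    for ver in (9, 10):
        for grp in config.outcome_mix:
            sel = (icd_version == ver) & (outcome == grp)
            if sel.any():
                codes[sel] = rng.choice(_ICD_POOLS[grp][ver], size=int(sel.sum()))

    zips = np.array([zcta_zip(z) for z in zcta_ids])
    cases = pd.DataFrame(
        {
            "case_id": np.arange(config.n_cases),
            "admission_date": admission,
            "residential_zip": zips,
            "hospital_zip": zips,
            "icd_codes": codes,
            "icd_version": icd_version,
            "sex": _draw_categorical(rng, config.demographics["sex"], config.n_cases),
            "age_group": _draw_categorical(
                rng, config.demographics["age_group"], config.n_cases
            ),
            "language": _draw_categorical(
                rng, config.demographics["language"], config.n_cases
            ),
            "race_ethnicity": _draw_categorical(
                rng, config.demographics["race_ethnicity"], config.n_cases
            ),
            "zcta_id": zcta_ids,
        }
    )
    for name, draw in flags.items():
        cases[name] = draw[z_pos.loc[cases["zcta_id"]].to_numpy()]
    cases.attrs["n_strata_resampled"] = n_resampled
    return cases


def simulate_strata(
    n_strata: int,
    beta: tuple[float, float, float],
    rng: np.random.Generator,
    stratum_sizes: tuple[int, ...] = (4, 5),
    heat_prob: float = 0.10,
    smoke_prob: float = 0.15,
    smoke_mean: float = 8.0,
    smoke_sd: float = 6.0,
    binary_smoke: bool = False,
) -> pd.DataFrame:
    """Simulate matched case-crossover strata directly at the design level.

    Each stratum has 4 or 5 rows (one calendar month's same-weekday days);
    row exposures are drawn i.i.d. — heat is Bernoulli(``heat_prob``),
    smoke is zero with probability ``1 - smoke_prob`` and lognormal
    otherwise (or exactly 1 when ``binary_smoke`` is set, for exposure
    contrasts defined on an indicator) — and the case row is sampled
    within each stratum with
    probability proportional to ``exp(bH*xH + bS*xS + bHS*xH*xS)``.  This is
    the same data-generating process as :func:`simulate_cases` without the
    raster stage; it exists for fast parameter-recovery and coverage
    studies.

    Returns a design table with ``stratum_id, is_case, x_heat, x_smoke``.
    """
    bH, bS, bHS = beta
    sizes = rng.choice(stratum_sizes, size=n_strata)
    total = int(sizes.sum())
    stratum_id = np.repeat(np.arange(n_strata), sizes)

    x_heat = (rng.random(total) < heat_prob).astype(float)
    has_smoke = rng.random(total) < smoke_prob
    if binary_smoke:
        x_smoke = has_smoke.astype(float)
    else:
        sigma2 = np.log1p((smoke_sd / smoke_mean) ** 2)
        mu = np.log(smoke_mean) - sigma2 / 2.0
        x_smoke = np.where(
            has_smoke, rng.lognormal(mu, np.sqrt(sigma2), total), 0.0
        )

    eta = bH * x_heat + bS * x_smoke + bHS * x_heat * x_smoke
    score = eta + rng.gumbel(size=total)
    order = np.lexsort((-score, stratum_id))  # best score first within stratum
    starts = np.r_[0, np.cumsum(sizes)[:-1]]
    is_case = np.zeros(total, dtype=bool)
    is_case[order[starts]] = True

    return pd.DataFrame(
        {
            "stratum_id": stratum_id,
            "is_case": is_case,
            "x_heat": x_heat,
            "x_smoke": x_smoke,
        }
    )
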