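"""ZCTA-level daily exposure construction.

Builds the two exposures of the compound-hazard analysis from gridded
inputs:

* **wildfire-influenced PM2.5** — total PM2.5 minus the expected smoke-free
  concentration for that grid cell and calendar day, kept only on days when a
  smoke plume overlaps the cell and the total exceeds the expectation;
* **extreme heat** — daily maximum temperature above a month- and
  ZCTA-specific empirical percentile threshold (90th/95th/99th).

Gridded fields are population-weighted to ZIP Code Tabulation Areas before
thresholding, so ZCTA series reflect where people live within the ZCTA.

All tabular structures are plain pandas DataFrames in long format:
gridded fields are ``(cell_id, date, value)``, plume masks
``(cell_id, date, plume_present)``, exposure series
``(zcta_id, date, tmax, wf_pm25, heat_day)``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "UnresolvableBaselineError",
    "ZeroPopulationError",
    "MissingThresholdError",
    "mmdd_index",
    "smoke_free_baseline",
    "wf_influenced_pm25",
    "regrid_nearest",
    "population_weighted_zcta",
    "heat_thresholds",
    "flag_extreme_heat",
    "build_exposure_series",
]

# day-of-year keyed on a 365-day calendar; Feb 29 pools with Feb 28
_N_DOY = 365
_MONTH_STARTS = np.cumsum([0, 31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30])
_DOY_TO_MONTH_DAY = [
    (m + 1, d + 1)
    for m, length in enumerate([31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31])
    for d in range(length)
]


class UnresolvableBaselineError(ValueError):
    """No smoke-free observation within the maximum fallback window."""


class ZeroPopulationError(ValueError):
    """A ZCTA with zero total population cannot be population-weighted."""


class MissingThresholdError(KeyError):
    """A (ZCTA, month) pair in the series has no heat threshold."""


def mmdd_index(dates: pd.Series | pd.DatetimeIndex) -> np.ndarray:
    """Map dates to a 0..364 calendar-day index, Feb 29 -> Feb 28's slot."""
    dates = pd.DatetimeIndex(dates)
    month = dates.month.to_numpy()
    day = np.minimum(
        dates.day.to_numpy(),
        np.where(month == 2, 28, 31),
    )
    return _MONTH_STARTS[month - 1] + day - 1


def smoke_free_baseline(
    pm25: pd.DataFrame, plumes: pd.DataFrame, max_window: int = 15
) -> pd.DataFrame:
    """Expected smoke-free PM2.5 per grid cell and calendar day.

    For each (cell, month, day) the baseline is the mean of total PM2.5 over
    every study year on that calendar day with no plume present.  Calendar
    days with no smoke-free observation widen symmetrically (+-w days,
    circular over the year boundary, w = 1..``max_window``) until at least
    one observation is pooled.

    Returns a DataFrame with ``cell_id, month, day, expected_pm25, n_obs,
    window``.  Raises :class:`UnresolvableBaselineError` if any cell has a
    calendar day whose +-``max_window`` window is entirely plume-covered.
    """
    df = pm25.merge(
        plumes[["cell_id", "date", "plume_present"]],
        on=["cell_id", "date"],
        how="left",
    )
    df["plume_present"] = df["plume_present"].fillna(False).astype(bool)

    cells = np.sort(df["cell_id"].unique())
    cell_pos = pd.Series(np.arange(len(cells)), index=cells)
    doy = mmdd_index(df["date"])
    rows = cell_pos.loc[df["cell_id"]].to_numpy()

    free = ~df["plume_present"].to_numpy()
    sums = np.zeros((len(cells), _N_DOY))
    counts = np.zeros((len(cells), _N_DOY))
    np.add.at(sums, (rows[free], doy[free]), df.loc[free, "value"].to_numpy())
    np.add.at(counts, (rows[free], doy[free]), 1.0)

    # only calendar days actually present in the input need a baseline
    observed = np.zeros((len(cells), _N_DOY), dtype=bool)
    observed[rows, doy] = True

    expected = np.full_like(sums, np.nan)
    n_obs = np.zeros_like(counts)
    window = np.zeros_like(counts)
    have = counts > 0
    expected[have] = sums[have] / counts[have]
    n_obs[have] = counts[have]

    missing = observed & ~have
    for w in range(1, max_window + 1):
        if not missing.any():
            break
        kernel = np.ones(2 * w + 1)
        wsums = ndimage.convolve1d(sums, kernel, axis=1, mode="wrap")
        wcounts = ndimage.convolve1d(counts, kernel, axis=1, mode="wrap")
        fill = missing & (wcounts > 0)
        expected[fill] = wsums[fill] / wcounts[fill]
        n_obs[fill] = wcounts[fill]
        window[fill] = w
        missing &= ~fill
    if missing.any():
        bad_cells = cells[missing.any(axis=1)]
        raise UnresolvableBaselineError(
            f"no smoke-free observation within +-{max_window} days for "
            f"cells {bad_cells.tolist()}"
        )

    r, c = np.nonzero(observed)
    months = np.array([_DOY_TO_MONTH_DAY[i][0] for i in c])
    days = np.array([_DOY_TO_MONTH_DAY[i][1] for i in c])
    return pd.DataFrame(
        {
            "cell_id": cells[r],
            "month": months,
            "day": days,
            "expected_pm25": expected[r, c],
            "n_obs": n_obs[r, c].astype(int),
            "window": window[r, c].astype(int),
        }
    )


def wf_influenced_pm25(
    pm25: pd.DataFrame, plumes: pd.DataFrame, baseline: pd.DataFrame
) -> pd.DataFrame:
    """Wildfire-influenced PM2.5: total minus expected smoke-free value on
    plume-overlapped exceedance days, zero otherwise (never negative)."""
    df = pm25.merge(
        plumes[["cell_id", "date", "plume_present"]],
        on=["cell_id", "date"],
        how="left",
    )
    df["plume_present"] = df["plume_present"].fillna(False).astype(bool)
    d = pd.DatetimeIndex(df["date"])
    df["month"] = d.month
    df["day"] = np.where((d.month == 2) & (d.day == 29), 28, d.day)
    df = df.merge(
        baseline[["cell_id", "month", "day", "expected_pm25"]],
        on=["cell_id", "month", "day"],
        how="left",
        validate="many_to_one",
    )
    if df["expected_pm25"].isna().any():
        missing = df.loc[df["expected_pm25"].isna(), ["cell_id", "month", "day"]]
        raise UnresolvableBaselineError(
            f"baseline not resolved for {len(missing)} (cell, day) rows, "
            f"e.g. {missing.iloc[0].to_dict()}"
        )
    value = np.where(
        df["plume_present"].to_numpy()
        & (df["value"].to_numpy() > df["expected_pm25"].to_numpy()),
        df["value"].to_numpy() - df["expected_pm25"].to_numpy(),
        0.0,
    )
    return pd.DataFrame(
        {"cell_id": df["cell_id"], "date": df["date"], "value": value}
    )


def regrid_nearest(
    field: pd.DataFrame, factor: int, grid_shape: tuple[int, int]
) -> pd.DataFrame:
    """Nearest-neighbor block replication of a coarse field onto a finer grid.

    ``grid_shape = (nx, ny)`` are the coarse grid's column/row counts with
    row-major cell ids (``cell_id = row * nx + col``).  Each fine cell takes
    the value of its containing coarse cell; ``factor=1`` is the identity.
    """
    if factor < 1 or int(factor) != factor:
        raise ValueError(f"resolution factor must be a positive integer, got {factor}")
    factor = int(factor)
    if factor == 1:
        return field.copy()
    nx, ny = grid_shape
    fine_nx = nx * factor
    rows_f, cols_f = np.divmod(np.arange(fine_nx * ny * factor), fine_nx)
    coarse_of_fine = (rows_f // factor) * nx + (cols_f // factor)
    mapping = pd.DataFrame(
        {"fine_cell_id": np.arange(fine_nx * ny * factor), "cell_id": coarse_of_fine}
    )
    out = mapping.merge(field, on="cell_id", how="inner")
    out = out.drop(columns="cell_id").rename(columns={"fine_cell_id": "cell_id"})
    cols = ["cell_id"] + [c for c in field.columns if c != "cell_id"]
    return out[cols].sort_values(
        ["cell_id"] + (["date"] if "date" in out.columns else [])
    ).reset_index(drop=True)


def population_weighted_zcta(
    field: pd.DataFrame, crosswalk: pd.DataFrame, value_name: str = "value"
) -> pd.DataFrame:
    """Population-weighted aggregation of a gridded field to ZCTAs.

    value(zcta, date) = sum over cells of value(cell, date) * pop(cell) /
    pop(zcta); the weights form a convex combination within each ZCTA.
    """
    pop_tot = crosswalk.groupby("zcta_id")["population"].sum()
    zero = pop_tot[pop_tot <= 0]
    if len(zero):
        raise ZeroPopulationError(
            f"ZCTA(s) with zero population: {zero.index.tolist()}"
        )
    xw = crosswalk.copy()
    xw["weight"] = xw["population"] / pop_tot.loc[xw["zcta_id"]].to_numpy()
    df = field.merge(xw[["cell_id", "zcta_id", "weight"]], on="cell_id")
    df["_wv"] = df["value"] * df["weight"]
    out = (
        df.groupby(["zcta_id", "date"], as_index=False)["_wv"]
        .sum()
        .rename(columns={"_wv": value_name})
    )
    return out


def heat_thresholds(
    series: pd.DataFrame,
    percentiles: tuple[int, ...] = (90, 95, 99),
    min_obs: int = 28,
) -> pd.DataFrame:
    """Month- and ZCTA-specific Tmax percentile thresholds.

    Empirical quantiles use linear interpolation between order statistics on
    all daily values for that ZCTA and calendar month pooled across study
    years.  Requires at least ``min_obs`` observations per (ZCTA, month).
    """
    df = series[["zcta_id", "date", "tmax"]].copy()
    df["month"] = pd.DatetimeIndex(df["date"]).month
    sizes = df.groupby(["zcta_id", "month"]).size()
    too_few = sizes[sizes < min_obs]
    if len(too_few):
        raise ValueError(
            f"fewer than {min_obs} Tmax observations for (zcta, month) pairs: "
            f"{too_few.index.tolist()[:10]}"
        )
    rows = []
    for (zcta, month), grp in df.groupby(["zcta_id", "month"]):
        vals = grp["tmax"].to_numpy()
        for p in percentiles:
            rows.append(
                (zcta, month, int(p), float(np.percentile(vals, p, method="linear")))
            )
    return pd.DataFrame(rows, columns=["zcta_id", "month", "percentile", "threshold_F"])


def flag_extreme_heat(
    series: pd.DataFrame, thresholds: pd.DataFrame, percentile: int = 95
) -> pd.DataFrame:
    """Flag extreme-heat days: Tmax strictly greater than the (ZCTA, month)
    threshold at the chosen percentile."""
    thr = thresholds[thresholds["percentile"] == percentile]
    if thr.empty:
        raise MissingThresholdError(f"no thresholds at percentile {percentile}")
    out = series.copy()
    out["month"] = pd.DatetimeIndex(out["date"]).month
    out = out.merge(
        thr[["zcta_id", "month", "threshold_F"]],
        on=["zcta_id", "month"],
        how="left",
        validate="many_to_one",
    )
    if out["threshold_F"].isna().any():
        missing = out.loc[out["threshold_F"].isna(), ["zcta_id", "month"]]
        raise MissingThresholdError(
            f"missing threshold for (zcta, month) pairs, e.g. "
            f"{missing.iloc[0].to_dict()}"
        )
    out["heat_day"] = out["tmax"].to_numpy() > out["threshold_F"].to_numpy()
    return out.drop(columns=["month", "threshold_F"])


def build_exposure_series(
    tmax: pd.DataFrame,
    pm25: pd.DataFrame,
    plumes: pd.DataFrame,
    crosswalk: pd.DataFrame,
    percentiles: tuple[int, ...] = (90, 95, 99),
    heat_percentile: int = 95,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """End-to-end exposure pipeline on gridded inputs.

    Computes smoke-free baselines, wildfire-influenced PM2.5, population
    weighting of both hazards to ZCTAs, percentile heat thresholds, and the
    extreme-heat flag.  Returns ``(exposure_series, thresholds)``.
    """
    baseline = smoke_free_baseline(pm25, plumes)
    wf = wf_influenced_pm25(pm25, plumes, baseline)
    tz = population_weighted_zcta(tmax, crosswalk, value_name="tmax")
    wz = population_weighted_zcta(wf, crosswalk, value_name="wf_pm25")
    series = tz.merge(wz, on=["zcta_id", "date"], how="inner")
    thresholds = heat_thresholds(series, percentiles=percentiles)
    series = flag_extreme_heat(series, thresholds, percentile=heat_percentile)
    return series, thresholds
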