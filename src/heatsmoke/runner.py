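"""Study orchestration: the 4x4 lag grid per outcome, stratified analyses
with small-cell suppression, and tabular "heat-map" outputs.

For each outcome and each of the 16 (heat lag, smoke lag) combinations the
runner builds time-stratified case-crossover strata, fits the conditional
logistic interaction model, and computes the multiplicative and additive
interaction measures.  Cells whose joint-exposed case count falls below the
suppression threshold carry counts but no estimates.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import cohort, inference

__all__ = [
    "RunConfig",
    "CellResult",
    "LagGridResult",
    "LAG_PAIRS",
    "run_lag_grid",
    "run_stratified",
    "write_report",
    "results_to_frame",
]

LAG_PAIRS = [(x, y) for x in range(4) for y in range(4)]

# stratification factors: individual-level columns and community-level flags
_FACTOR_COLUMNS = {
    "sex": "sex",
    "age_group": "age_group",
    "language": "language",
    "race_ethnicity": "race_ethnicity",
    "poverty": "high_poverty",
    "education": "low_education",
    "rurality": "rural",
}
_FLAG_LEVELS = {
    "poverty": {True: "higher_poverty", False: "lesser_poverty"},
    "education": {True: "lower_education", False: "higher_education"},
    "rurality": {True: "rural", False: "urban"},
}


@dataclass(frozen=True)
class RunConfig:
    """One study configuration.

    ``months=(5, 11)`` restricts case days to May–November (the compound
    hazard season); ``exclude_years`` drops whole admission years (2020 by
    default, the pandemic year).  ``suppression_min_exposed`` suppresses
    cells with fewer exposed cases; the counting rule is ``"joint"``
    (lag-assigned heat AND smoke exposure, the binding constraint for
    interaction cells) or ``"either"``.
    """

    outcomes: tuple[str, ...] = cohort.OUTCOMES
    heat_percentile: int = 95
    smoke_coding: str = "continuous"
    months: tuple[int, int] | None = (5, 11)
    years: tuple[int, int] | None = None
    exclude_years: tuple[int, ...] = (2020,)
    strata_factors: tuple[str, ...] = ()
    suppression_min_exposed: int = 10
    exposed_rule: str = "joint"
    delta: float = 1.0
    seed: int = 0

    def __post_init__(self):
        for o in self.outcomes:
            if o not in cohort.OUTCOMES:
                raise ValueError(f"unknown outcome: {o!r}")
        if self.smoke_coding not in ("continuous", "binary_gt0", "binary_gt12"):
            raise ValueError(f"unknown smoke coding: {self.smoke_coding!r}")
        if self.heat_percentile not in (90, 95, 99):
            raise ValueError("heat_percentile must be one of 90, 95, 99")
        if self.suppression_min_exposed < 0:
            raise ValueError("suppression_min_exposed must be >= 0")
        if self.exposed_rule not in ("joint", "either"):
            raise ValueError(f"unknown exposed-count rule: {self.exposed_rule!r}")
        for f in self.strata_factors:
            if f not in _FACTOR_COLUMNS:
                raise ValueError(f"unknown stratification factor: {f!r}")


@dataclass
class CellResult:
    heat_lag: int
    smoke_lag: int
    n_strata: int
    n_exposed_cases: int
    suppressed: bool
    estimates: inference.InteractionEstimates | None = None
    message: str = ""


@dataclass
class LagGridResult:
    outcome: str
    subset: str  # "all" or "<factor>=<level>"
    cells: dict[tuple[int, int], CellResult]
    n_cases: int
    log: cohort.ExclusionLog = field(default_factory=cohort.ExclusionLog)

    def cell(self, heat_lag: int, smoke_lag: int) -> CellResult:
        return self.cells[(heat_lag, smoke_lag)]


def _filter_calendar(cases: pd.DataFrame, config: RunConfig) -> pd.DataFrame:
    d = pd.to_datetime(cases["admission_date"])
    keep = np.ones(len(cases), dtype=bool)
    if config.years is not None:
        keep &= (d.dt.year >= config.years[0]) & (d.dt.year <= config.years[1])
    if config.exclude_years:
        keep &= ~d.dt.year.isin(config.exclude_years).to_numpy()
    if config.months is not None:
        keep &= (d.dt.month >= config.months[0]) & (d.dt.month <= config.months[1])
    return cases.loc[keep].reset_index(drop=True)


def _outcome_labels(cases: pd.DataFrame) -> pd.DataFrame:
    """One boolean column per outcome; a record with multiple qualifying
    codes enters each outcome-specific analysis once."""
    out = pd.DataFrame(index=cases.index)
    labels = [
        cohort.classify_outcome(code, ver)
        for code, ver in zip(cases["icd_codes"], cases["icd_version"])
    ]
    for o in cohort.OUTCOMES:
        out[o] = [o in s for s in labels]
    return out


def _exposed_count(design: pd.DataFrame, rule: str) -> int:
    case_rows = design[design["is_case"]]
    heat = case_rows["x_heat"].to_numpy() > 0
    smoke = case_rows["x_smoke"].to_numpy() > 0
    joint = heat & smoke
    return int(joint.sum()) if rule == "joint" else int((heat | smoke).sum())


def _grid_for_cases(
    cases: pd.DataFrame,
    exposures: pd.DataFrame,
    config: RunConfig,
    outcome: str,
    subset: str,
    log: cohort.ExclusionLog,
) -> LagGridResult:
    cells: dict[tuple[int, int], CellResult] = {}
    if cases.empty:
        for lag in LAG_PAIRS:
            cells[lag] = CellResult(*lag, 0, 0, True, message="no cases")
        return LagGridResult(outcome, subset, cells, 0, log)

    referents = cohort.build_referent_table(cases)
    for lag in LAG_PAIRS:
        design, n_dropped = cohort.attach_lagged_exposures(
            referents, exposures, lag, config.smoke_coding
        )
        log.n_strata_dropped_missing_exposure += n_dropped
        n_strata = design["stratum_id"].nunique()
        n_exposed = _exposed_count(design, config.exposed_rule)
        cell = CellResult(lag[0], lag[1], n_strata, n_exposed,
                          suppressed=n_exposed < config.suppression_min_exposed)
        if not cell.suppressed:
            try:
                fit = inference.fit_clogit(design)
                if fit.converged:
                    cell.estimates = inference.interaction_measures(
                        fit, delta=config.delta
                    )
                else:
                    cell.message = fit.message
            except (inference.DegenerateDesignError,
                    inference.SingularHessianError) as err:
                cell.message = str(err)
        cells[lag] = cell
    return LagGridResult(outcome, subset, cells, len(cases), log)


def run_lag_grid(
    cases: pd.DataFrame,
    exposures: pd.DataFrame,
    config: RunConfig,
    zip_to_zcta: dict | None = None,
) -> dict[str, LagGridResult]:
    """Fit the full 16-cell lag grid for every requested outcome.

    ``cases`` must carry residential/hospital ZIPs (resolved through
    ``zip_to_zcta``) or an already-assigned ``zcta_id`` column.
    Deterministic given identical inputs.
    """
    if "zcta_id" in cases.columns and zip_to_zcta is None:
        assigned, log = cases.copy(), cohort.ExclusionLog(
            n_input=len(cases), n_included=len(cases)
        )
    else:
        if zip_to_zcta is None:
            raise ValueError("zip_to_zcta mapping required when cases lack zcta_id")
        assigned, log = cohort.assign_zcta(
            cases, zip_to_zcta, set(exposures["zcta_id"].unique())
        )
    assigned = _filter_calendar(assigned, config)
    labels = _outcome_labels(assigned)

    results = {}
    for outcome in config.outcomes:
        sub = assigned.loc[labels[outcome].to_numpy()].reset_index(drop=True)
        results[outcome] = _grid_for_cases(
            sub, exposures, config, outcome, "all", dataclasses.replace(log)
        )
    return results


def run_stratified(
    cases: pd.DataFrame,
    exposures: pd.DataFrame,
    config: RunConfig,
    zip_to_zcta: dict | None = None,
) -> list[LagGridResult]:
    """One lag grid per stratification-factor level, refit on the subset.

    Community factors use the printed binary cutoffs carried on the records
    (poverty >= 25% of households, low education >= 50% with at most a high
    school education, rural >= 50% rural composition).  Levels with zero
    cases yield fully suppressed grids, not errors.
    """
    if not config.strata_factors:
        raise ValueError("strata_factors must be non-empty for stratified runs")
    results: list[LagGridResult] = []
    for factor in config.strata_factors:
        col = _FACTOR_COLUMNS[factor]
        values = cases[col]
        levels = (
            [True, False] if factor in _FLAG_LEVELS else sorted(values.unique())
        )
        for level in levels:
            label = (
                _FLAG_LEVELS[factor][level]
                if factor in _FLAG_LEVELS
                else str(level)
            )
            sub = cases.loc[values == level].reset_index(drop=True)
            sub_results = run_lag_grid(sub, exposures, config, zip_to_zcta)
            for outcome, grid in sub_results.items():
                grid.subset = f"{factor}={label}"
                results.append(grid)
    return results


def _ci_dict(e: inference.EstimateCI) -> dict:
    return dataclasses.asdict(e)


def _grid_to_dict(grid: LagGridResult) -> dict:
    cells = []
    for (x, y), cell in sorted(grid.cells.items()):
        d = {
            "heat_lag": x,
            "smoke_lag": y,
            "n_strata": cell.n_strata,
            "n_exposed_cases": cell.n_exposed_cases,
            "suppressed": cell.suppressed,
            "message": cell.message,
        }
        if cell.estimates is not None:
            d["estimates"] = dataclasses.asdict(cell.estimates)
        cells.append(d)
    return {
        "outcome": grid.outcome,
        "subset": grid.subset,
        "n_cases": grid.n_cases,
        "cells": cells,
        "log": dataclasses.asdict(grid.log),
    }


def results_to_frame(grids: list[LagGridResult]) -> pd.DataFrame:
    """Flat table of AP estimates across grids (one row per cell)."""
    rows = []
    for grid in grids:
        for (x, y), cell in sorted(grid.cells.items()):
            row = {
                "outcome": grid.outcome,
                "subset": grid.subset,
                "heat_lag": x,
                "smoke_lag": y,
                "n_strata": cell.n_strata,
                "n_exposed_cases": cell.n_exposed_cases,
                "suppressed": cell.suppressed,
            }
            if cell.estimates is not None:
                ap = cell.estimates.ap
                row.update(
                    ap=ap.estimate, ap_ci_low=ap.ci_low, ap_ci_high=ap.ci_high,
                    ap_p=ap.p_two_sided,
                    reri=cell.estimates.reri.estimate,
                    or01=cell.estimates.or01.estimate,
                    or10=cell.estimates.or10.estimate,
                    or11=cell.estimates.or11.estimate,
                    multiplicative=cell.estimates.multiplicative.estimate,
                )
            rows.append(row)
    return pd.DataFrame(rows)


def write_report(grids: list[LagGridResult], output_dir: str | Path) -> list[Path]:
    """Write per-grid AP tables (the tabular twin of the heat-map figures),
    a full-estimates JSON, and a run log with exclusion/suppression
    accounting.  Returns the list of files written."""
    outdir = Path(output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []

    for grid in grids:
        tag = grid.outcome if grid.subset == "all" else f"{grid.outcome}_{grid.subset}"
        tag = tag.replace("=", "-").replace(" ", "_")
        frame = results_to_frame([grid])
        path = outdir / f"ap_grid_{tag}.csv"
        frame.to_csv(path, index=False)
        written.append(path)

    jpath = outdir / "estimates.json"
    with open(jpath, "w") as fh:
        json.dump([_grid_to_dict(g) for g in grids], fh, indent=1, sort_keys=True)
    written.append(jpath)

    lpath = outdir / "run_log.txt"
    with open(lpath, "w") as fh:
        n_suppressed = sum(
            c.suppressed for g in grids for c in g.cells.values()
        )
        n_cells = sum(len(g.cells) for g in grids)
        fh.write(f"grids: {len(grids)}\n")
        fh.write(f"cells fitted: {n_cells - n_suppressed} of {n_cells} "
                 f"({n_suppressed} suppressed)\n")
        fh.write("note: raw (uncorrected) p-values across all cells; adjust "
                 "post hoc if desired\n")
        for g in grids:
            log = g.log
            fh.write(
                f"{g.outcome} [{g.subset}]: cases={g.n_cases} "
                f"input={log.n_input} included={log.n_included} "
                f"excluded_zip={log.n_excluded_zip} "
                f"excluded_no_exposure={log.n_excluded_no_exposure} "
                f"strata_dropped_missing_exposure="
                f"{log.n_strata_dropped_missing_exposure}\n"
            )
    written.append(lpath)
    return written
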