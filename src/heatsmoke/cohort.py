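"""Case-crossover cohort construction.

Turns hospitalization records into analyzable matched strata:

* outcome classification from ICD-9 / ICD-10 diagnosis codes,
* ZCTA assignment from residential ZIP with hospital-ZIP fallback,
* time-stratified referent selection (same day of week, month and year),
* attachment of lagged heat / smoke exposures to every case and referent day.

The design table produced here is the direct input to
:mod:`heatsmoke.inference`.
"""

from __future__ import annotations

import calendar
import datetime as dt
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "OUTCOMES",
    "ICD9_RANGES",
    "ICD10_RANGES",
    "IcdParseError",
    "MissingExposureError",
    "ExclusionLog",
    "classify_outcome",
    "assign_zcta",
    "build_referents",
    "build_referent_table",
    "attach_lagged_exposures",
    "build_design",
]

OUTCOMES = ("all_natural", "respiratory", "cardiovascular", "cerebrovascular", "renal")

# Cause-specific diagnosis category ranges (3-character categories, inclusive).
# Subcodes (e.g. J45.9, 4660) inherit the category's classification.
ICD10_RANGES: dict[str, list[tuple[str, str]]] = {
    "respiratory": [
        ("J00", "J06"), ("J12", "J18"), ("J20", "J22"), ("J30", "J31"),
        ("J33", "J34"), ("J38", "J39"), ("J40", "J47"), ("J80", "J86"),
        ("J90", "J92"), ("J94", "J94"), ("J96", "J99"), ("R04", "R07"),
        ("R09", "R09"),
    ],
    "cardiovascular": [
        ("I00", "I02"), ("I05", "I16"), ("I20", "I28"), ("I30", "I5A"),
        ("I70", "I79"),
    ],
    "cerebrovascular": [("I60", "I69")],
    "renal": [
        ("N00", "N08"), ("N10", "N13"), ("N15", "N23"), ("N25", "N29"),
        ("R30", "R39"),
    ],
}

ICD9_RANGES: dict[str, list[tuple[int, int]]] = {
    "respiratory": [
        (460, 466), (471, 472), (477, 478), (480, 487), (490, 496),
        (511, 511), (513, 519), (786, 786),
    ],
    "cardiovascular": [(390, 398), (401, 417), (420, 429), (440, 449)],
    "cerebrovascular": [(430, 438)],
    "renal": [(580, 589), (591, 599), (788, 788)],
}

# ICD-10 chapters counted as natural-cause morbidity.  S/T (injury, poisoning),
# V–Y (external causes), U (special purposes) and Z (status/contact) are
# excluded, mirroring the exclusion of accidental conditions due to trauma,
# injury or poison.
_NATURAL_ICD10_LETTERS = set("ABCDEFGHIJKLMNOPQR")

_ICD10_RE = re.compile(r"^[A-Z][0-9][0-9A-Z]")
_ICD9_RE = re.compile(r"^[0-9]{3}")


class IcdParseError(ValueError):
    """Raised for a diagnosis code that cannot be parsed."""


class MissingExposureError(KeyError):
    """Raised when an exposure series lacks a required (ZCTA, date) row."""


def classify_outcome(icd_code: str, icd_version: int) -> set[str]:
    """Map one diagnosis code to the set of outcome labels it qualifies for.

    Membership is decided on the code's 3-character category (dots and
    subcode digits stripped), so ``"J45.9"`` classifies like ``"J45"``.
    Natural-cause codes always receive ``"all_natural"``; external-cause and
    injury codes return the empty set.
    """
    code = str(icd_code).strip().upper().replace(".", "")
    if not code:
        raise IcdParseError(f"empty ICD code: {icd_code!r}")
    labels: set[str] = set()
    if icd_version == 10:
        if not _ICD10_RE.match(code):
            raise IcdParseError(f"malformed ICD-10 code: {icd_code!r}")
        cat = code[:3]
        if cat[0] not in _NATURAL_ICD10_LETTERS:
            return set()
        for outcome, ranges in ICD10_RANGES.items():
            for lo, hi in ranges:
                if lo[0] == cat[0] and lo <= cat <= hi:
                    labels.add(outcome)
                    break
        labels.add("all_natural")
        return labels
    if icd_version == 9:
        if code[0] in ("E", "V"):
            # external-cause (E) and supplementary (V) classifications
            if re.match(r"^[EV][0-9]{2,3}", code):
                return set()
            raise IcdParseError(f"malformed ICD-9 code: {icd_code!r}")
        if not _ICD9_RE.match(code):
            raise IcdParseError(f"malformed ICD-9 code: {icd_code!r}")
        cat = int(code[:3])
        if cat >= 800:  # injury and poisoning
            return set()
        for outcome, ranges in ICD9_RANGES.items():
            for lo, hi in ranges:
                if lo <= cat <= hi:
                    labels.add(outcome)
                    break
        labels.add("all_natural")
        return labels
    raise IcdParseError(f"unsupported ICD version: {icd_version!r}")


@dataclass
class ExclusionLog:
    """Accounting of records entering and leaving the cohort pipeline."""

    n_input: int = 0
    n_included: int = 0
    n_hospital_fallback: int = 0
    n_excluded_zip: int = 0
    n_excluded_no_exposure: int = 0
    n_strata_dropped_missing_exposure: int = 0
    notes: list[str] = field(default_factory=list)

    def check_identity(self) -> bool:
        return self.n_input == (
            self.n_included + self.n_excluded_zip + self.n_excluded_no_exposure
        )


def assign_zcta(
    cases: pd.DataFrame,
    zip_to_zcta: dict,
    exposure_zctas: set | None = None,
) -> tuple[pd.DataFrame, ExclusionLog]:
    """Assign each record a ZCTA from its residential ZIP.

    Unmatched residential ZIPs fall back to the hospital ZIP; records still
    unmatched, or mapped to a ZCTA with no exposure data, are excluded and
    counted.  Exclusion is a logged outcome, never an exception.
    """
    log = ExclusionLog(n_input=len(cases))
    res = cases["residential_zip"].map(zip_to_zcta)
    hosp = cases["hospital_zip"].map(zip_to_zcta)
    zcta = res.where(res.notna(), hosp)
    log.n_hospital_fallback = int((res.isna() & hosp.notna()).sum())
    matched = zcta.notna()
    log.n_excluded_zip = int((~matched).sum())
    out = cases.loc[matched].copy()
    out["zcta_id"] = zcta.loc[matched]
    if exposure_zctas is not None:
        has_exp = out["zcta_id"].isin(exposure_zctas)
        log.n_excluded_no_exposure = int((~has_exp).sum())
        out = out.loc[has_exp]
    log.n_included = len(out)
    return out.reset_index(drop=True), log


def build_referents(case_date: dt.date | pd.Timestamp) -> list[dt.date]:
    """Time-stratified referents: all same-day-of-week dates in the case's
    calendar month and year, excluding the case date itself (3 or 4 dates)."""
    d = pd.Timestamp(case_date)
    n_days = calendar.monthrange(d.year, d.month)[1]
    first = ((d.day - 1) % 7) + 1
    return [
        dt.date(d.year, d.month, day)
        for day in range(first, n_days + 1, 7)
        if day != d.day
    ]


def build_referent_table(cases: pd.DataFrame) -> pd.DataFrame:
    """Vectorized referent expansion for a whole case table.

    Returns one row per case/referent day with columns ``stratum_id``
    (= case index), ``zcta_id``, ``date``, ``is_case``.  Requires columns
    ``admission_date`` (datetime-like) and ``zcta_id``.
    """
    dates = pd.to_datetime(cases["admission_date"])
    day = dates.dt.day.to_numpy()
    month_len = dates.dt.days_in_month.to_numpy()
    first = ((day - 1) % 7) + 1
    sid = np.arange(len(cases))

    frames = []
    # same-weekday day numbers are first, first+7, ..., at most 5 per month
    for k in range(5):
        cand = first + 7 * k
        ok = cand <= month_len
        offs = (cand - day)[ok]
        frames.append(
            pd.DataFrame(
                {
                    "stratum_id": sid[ok],
                    "date": dates.to_numpy()[ok] + offs.astype("timedelta64[D]"),
                    "is_case": offs == 0,
                }
            )
        )
    out = pd.concat(frames, ignore_index=True)
    out = out.merge(
        pd.DataFrame({"stratum_id": sid, "zcta_id": cases["zcta_id"].to_numpy()}),
        on="stratum_id",
    )
    return out.sort_values(["stratum_id", "is_case", "date"],
                           ascending=[True, False, True]).reset_index(drop=True)


def _smoke_code(values: np.ndarray, coding: str) -> np.ndarray:
    if coding == "continuous":
        return values.astype(float)
    if coding == "binary_gt0":
        return (values > 0).astype(float)
    if coding == "binary_gt12":
        return (values > 12.0).astype(float)  # strict >, heavy-plume cutoff
    raise ValueError(f"unknown smoke coding: {coding!r}")


def attach_lagged_exposures(
    strata: pd.DataFrame,
    exposures: pd.DataFrame,
    lags: tuple[int, int],
    smoke_coding: str = "continuous",
) -> tuple[pd.DataFrame, int]:
    """Attach lag-assigned exposures to a referent table.

    ``lags = (X, Y)`` reads the binary heat indicator X days before, and
    wildfire-smoke PM2.5 Y days before, each case/referent date (lag 0 is the
    day itself).  Strata with any missing exposure row are dropped and
    counted; returns ``(design, n_strata_dropped)``.
    """
    heat_lag, smoke_lag = lags
    if not (0 <= heat_lag <= 3 and 0 <= smoke_lag <= 3):
        raise ValueError(f"lags must be in 0..3, got {lags}")
    exp = exposures.set_index(["zcta_id", "date"])
    heat = exp["heat_day"].astype(float)
    smoke = exp["wf_pm25"].astype(float)

    d = pd.to_datetime(strata["date"])
    idx_h = pd.MultiIndex.from_arrays(
        [strata["zcta_id"], d - pd.Timedelta(days=heat_lag)]
    )
    idx_s = pd.MultiIndex.from_arrays(
        [strata["zcta_id"], d - pd.Timedelta(days=smoke_lag)]
    )
    x_heat = heat.reindex(idx_h).to_numpy()
    x_smoke_raw = smoke.reindex(idx_s).to_numpy()

    out = strata.copy()
    out["x_heat"] = x_heat
    out["x_smoke"] = x_smoke_raw
    bad = out["x_heat"].isna() | out["x_smoke"].isna()
    dropped_ids = out.loc[bad, "stratum_id"].unique()
    out = out[~out["stratum_id"].isin(dropped_ids)].copy()
    out["x_smoke"] = _smoke_code(out["x_smoke"].to_numpy(), smoke_coding)
    out["x_interaction"] = out["x_heat"] * out["x_smoke"]
    return out.reset_index(drop=True), len(dropped_ids)


def build_design(
    cases: pd.DataFrame,
    exposures: pd.DataFrame,
    lags: tuple[int, int],
    smoke_coding: str = "continuous",
    months: tuple[int, int] | None = None,
) -> tuple[pd.DataFrame, int]:
    """Full cohort step: referent expansion plus lagged exposure attachment.

    ``months=(5, 11)`` restricts to case dates in May-November; referents
    share the month by construction.  Cases must carry ``zcta_id``.
    """
    cases = cases.reset_index(drop=True)
    if months is not None:
        m = pd.to_datetime(cases["admission_date"]).dt.month
        cases = cases[(m >= months[0]) & (m <= months[1])].reset_index(drop=True)
    if cases.empty:
        empty = pd.DataFrame(
            columns=["stratum_id", "zcta_id", "date", "is_case",
                     "x_heat", "x_smoke", "x_interaction"]
        )
        return empty, 0
    strata = build_referent_table(cases)
    return attach_lagged_exposures(strata, exposures, lags, smoke_coding)
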