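"""Cohort data model, validation, I/O and derived clinical measures.

The package works on long-format longitudinal tables: one row per individual
per visit carrying the three cJADAS-10 components —

* ``ajc``     active joint count (non-negative integer, capped at 10 for modelling),
* ``pga_cm``  physician's global assessment, 0–10 cm VAS,
* ``pge_cm``  patient or parent global evaluation, 0–10 cm VAS,

plus a per-individual covariate table (age, gender, ILAR category,
deprivation quintile, ...).  Visit times are in years from first
presentation; the canonical follow-up schedule is {0, 0.5, 1, 2, 3}.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "CANONICAL_VISITS",
    "OUTCOME_COLUMNS",
    "ILAR_CATEGORIES",
    "CohortTable",
    "read_cohort",
    "write_cohort",
    "mm_to_cm",
    "cap_ajc_10",
    "cjadas10",
    "assign_ilar",
    "imd_quintile",
    "snap_visit_times",
]

CANONICAL_VISITS = (0.0, 0.5, 1.0, 2.0, 3.0)
#: tolerance (years) within which an observed visit time is snapped to a
#: canonical visit; registry follow-up is only approximately annual.
SNAP_TOLERANCE = 0.125

OUTCOME_COLUMNS = ("ajc", "pga_cm", "pge_cm")

ILAR_CATEGORIES = (
    "systemic",
    "oligo_persistent",
    "oligo_extended",
    "rf_neg_poly",
    "rf_pos_poly",
    "enthesitis_related",
    "psoriatic",
    "undifferentiated",
)


@dataclass
class CohortTable:
    """Validated long-format cohort.

    Attributes
    ----------
    data
        One row per (individual, visit) with columns ``individual_id``,
        ``time_years`` and the three outcome columns (NaN = missing).
    covariates
        Per-individual table indexed by ``individual_id``.
    exclusion_report
        Bookkeeping from :func:`read_cohort`: rejected rows and dropped
        individuals with reasons.
    """

    data: pd.DataFrame
    covariates: pd.DataFrame = field(default_factory=pd.DataFrame)
    exclusion_report: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        required = {"individual_id", "time_years", *OUTCOME_COLUMNS}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"cohort table missing columns: {sorted(missing)}")
        dup = self.data.duplicated(subset=["individual_id", "time_years"])
        if dup.any():
            bad = self.data.loc[dup, ["individual_id", "time_years"]].head()
            raise ValueError(f"duplicate (individual_id, time_years) pairs, e.g.\n{bad}")

    @property
    def n_individuals(self) -> int:
        return self.data["individual_id"].nunique()

    def individual_ids(self) -> np.ndarray:
        return self.data["individual_id"].unique()

    def baseline(self, time: float = 0.0, tol: float = SNAP_TOLERANCE) -> pd.DataFrame:
        """Baseline visit rows (one per individual where present)."""
        mask = (self.data["time_years"] - time).abs() <= tol
        base = self.data.loc[mask].sort_values("time_years")
        return base.drop_duplicates(subset="individual_id", keep="first")


def mm_to_cm(vas_mm: float) -> float:
    """Convert a 0–100 mm VAS reading to the 0–10 cm scale."""
    arr = np.asarray(vas_mm, dtype=float)
    if np.any((arr < 0) | (arr > 100)):
        raise ValueError("VAS (mm) must lie in [0, 100]")
    out = arr / 10.0
    return float(out) if out.ndim == 0 else out


def cap_ajc_10(ajc: int) -> int:
    """Cap an active joint count at ten (the cJADAS-10 convention)."""
    arr = np.asarray(ajc)
    if np.any(arr < 0):
        raise ValueError("active joint count must be non-negative")
    out = np.minimum(arr, 10)
    return int(out) if out.ndim == 0 else out


def cjadas10(ajc, pga_cm, pge_cm):
    """cJADAS-10 = min(AJC, 10) + PGA + PGE, range 0–30.

    Returns NaN when any component is missing — the score is not computable
    at that visit.
    """
    ajc = np.asarray(ajc, dtype=float)
    pga = np.asarray(pga_cm, dtype=float)
    pge = np.asarray(pge_cm, dtype=float)
    if np.any((pga < 0) | (pga > 10)) or np.any((pge < 0) | (pge > 10)):
        raise ValueError("global scores must lie in [0, 10] cm")
    if np.any(ajc[~np.isnan(ajc)] < 0):
        raise ValueError("active joint count must be non-negative")
    out = np.minimum(ajc, 10.0) + pga + pge
    out = np.where(np.isnan(ajc) | np.isnan(pga) | np.isnan(pge), np.nan, out)
    return float(out) if out.ndim == 0 else out


def assign_ilar(timeline) -> str | None:
    """Assign the ILAR category from a per-individual timeline.

    ``timeline`` is a mapping or iterable of ``(time_years, category)``.
    The category recorded at 1 year is used when present; otherwise the
    category recorded closest in time to 1 year, with exact distance ties
    resolved toward the earlier (baseline-side) entry.
    """
    if hasattr(timeline, "items"):
        entries = list(timeline.items())
    else:
        entries = list(timeline)
    entries = [(float(t), c) for t, c in entries if c is not None and not pd.isna(c)]
    if not entries:
        return None
    times = [t for t, _ in entries]
    if len(set(times)) != len(times):
        raise ValueError("ILAR timeline has duplicate times")
    # distance to 1 year; ties -> earlier time wins
    entries.sort(key=lambda tc: (abs(tc[0] - 1.0), tc[0]))
    return entries[0][1]


def imd_quintile(rank: int, country_total: int) -> int:
    """Map a within-country deprivation rank to a quintile (1 = most deprived).

    Rank 1 is the most deprived small area; quintile = ceil(5·rank/total).
    """
    if country_total < 1:
        raise ValueError("country_total must be positive")
    if not 1 <= rank <= country_total:
        raise ValueError(f"rank {rank} outside 1..{country_total}")
    return math.ceil(5 * rank / country_total)


def snap_visit_times(times, canonical=CANONICAL_VISITS, tol: float = SNAP_TOLERANCE):
    """Snap observed visit times to the canonical schedule where within ``tol``.

    Times farther than ``tol`` from every canonical visit are left unchanged
    (the trajectory likelihood accepts arbitrary per-individual visit sets).
    """
    times = np.asarray(times, dtype=float)
    canonical = np.asarray(canonical, dtype=float)
    diff = np.abs(times[:, None] - canonical[None, :])
    j = np.argmin(diff, axis=1)
    snapped = np.where(diff[np.arange(times.size), j] <= tol, canonical[j], times)
    return snapped


_DEFAULT_SCHEMA = {
    "columns": {
        "individual_id": "individual_id",
        "time_years": "time_years",
        "ajc": "ajc",
        "pga": "pga_cm",
        "pge": "pge_cm",
    },
    "vas_units": "cm",          # or "mm": converted on read
    "covariate_columns": None,  # None -> every unmapped column, taken at baseline
    "snap_tolerance": SNAP_TOLERANCE,
}


def read_cohort(path, schema_config: dict | None = None) -> CohortTable:
    """Read and validate a long-format cohort CSV.

    Rows violating range invariants (negative counts, VAS outside bounds,
    negative times) are rejected with a per-row reason; individuals without a
    single non-missing outcome at any visit are dropped and counted.  The
    full accounting lands in ``CohortTable.exclusion_report``.
    """
    schema = dict(_DEFAULT_SCHEMA)
    if schema_config:
        schema.update(schema_config)
        if "columns" in schema_config:
            cols = dict(_DEFAULT_SCHEMA["columns"])
            cols.update(schema_config["columns"])
            schema["columns"] = cols

    raw = pd.read_csv(path)
    colmap = schema["columns"]
    missing = [src for src in colmap.values() if src not in raw.columns]
    if missing:
        raise ValueError(f"schema error: columns {missing} not present in {path}")

    df = pd.DataFrame({
        "individual_id": raw[colmap["individual_id"]],
        "time_years": pd.to_numeric(raw[colmap["time_years"]], errors="coerce"),
        "ajc": pd.to_numeric(raw[colmap["ajc"]], errors="coerce"),
        "pga_cm": pd.to_numeric(raw[colmap["pga"]], errors="coerce"),
        "pge_cm": pd.to_numeric(raw[colmap["pge"]], errors="coerce"),
    })
    if schema["vas_units"] == "mm":
        df["pga_cm"] = df["pga_cm"] / 10.0
        df["pge_cm"] = df["pge_cm"] / 10.0
    elif schema["vas_units"] != "cm":
        raise ValueError("vas_units must be 'mm' or 'cm'")

    vas_hi = 10.0
    reasons = pd.Series("", index=df.index)
    bad_time = df["time_years"].isna() | (df["time_years"] < 0)
    bad_ajc = df["ajc"].notna() & ((df["ajc"] < 0) | (df["ajc"] % 1 != 0))
    bad_pga = df["pga_cm"].notna() & ((df["pga_cm"] < 0) | (df["pga_cm"] > vas_hi))
    bad_pge = df["pge_cm"].notna() & ((df["pge_cm"] < 0) | (df["pge_cm"] > vas_hi))
    reasons[bad_time] += "time;"
    reasons[bad_ajc | bad_pga | bad_pge] += "range;"
    bad = reasons != ""

    rejected = [
        {"row": int(i), "individual_id": str(df.at[i, "individual_id"]),
         "reason": reasons[i].rstrip(";")}
        for i in df.index[bad]
    ]
    df = df.loc[~bad].copy()

    dup = df.duplicated(subset=["individual_id", "time_years"])
    if dup.any():
        raise ValueError("validation error: duplicate (individual_id, time_years) rows")

    df["time_years"] = snap_visit_times(
        df["time_years"].to_numpy(), tol=schema["snap_tolerance"])
    # snapping can merge two nearby visits into one canonical slot
    dup = df.duplicated(subset=["individual_id", "time_years"])
    if dup.any():
        raise ValueError("validation error: duplicate visits after time snapping")

    has_outcome = df[list(OUTCOME_COLUMNS)].notna().any(axis=1)
    n_obs_per_id = has_outcome.groupby(df["individual_id"]).sum()
    dropped_ids = n_obs_per_id.index[n_obs_per_id == 0].tolist()
    df = df[~df["individual_id"].isin(dropped_ids)].reset_index(drop=True)

    cov_cols = schema["covariate_columns"]
    if cov_cols is None:
        cov_cols = [c for c in raw.columns if c not in set(colmap.values())]
    covariates = pd.DataFrame()
    if cov_cols:
        cov = raw[[colmap["individual_id"], colmap["time_years"], *cov_cols]].copy()
        cov = cov.rename(columns={colmap["individual_id"]: "individual_id",
                                  colmap["time_years"]: "time_years"})
        cov = cov.sort_values("time_years").groupby("individual_id").first()
        covariates = cov.drop(columns=["time_years"]).loc[
            lambda x: x.index.isin(df["individual_id"].unique())]

    report = {
        "n_rows_read": int(len(raw)),
        "n_rows_rejected": len(rejected),
        "rejected_rows": rejected,
        "n_individuals_dropped_no_outcome": len(dropped_ids),
        "dropped_individuals": [str(i) for i in dropped_ids],
    }
    return CohortTable(data=df, covariates=covariates, exclusion_report=report)


def write_cohort(cohort: CohortTable, path, report_path=None) -> None:
    """Write the normalized cohort CSV (canonical names, cm units, capped AJC).

    Adds ``ajc10`` (count capped at ten) and ``cjadas10`` columns; optionally
    writes the JSON exclusion report alongside.
    """
    out = cohort.data.copy()
    out["ajc10"] = np.minimum(out["ajc"], 10)
    out["cjadas10"] = np.where(
        out[list(OUTCOME_COLUMNS)].notna().all(axis=1),
        np.minimum(out["ajc"], 10) + out["pga_cm"] + out["pge_cm"],
        np.nan,
    )
    if not cohort.covariates.empty:
        out = out.merge(cohort.covariates, left_on="individual_id",
                        right_index=True, how="left")
    out.to_csv(path, index=False)
    if report_path is not None:
        Path(report_path).write_text(json.dumps(cohort.exclusion_report, indent=2))
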