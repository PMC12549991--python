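"""Readers, writers, and validation for the pipeline's tabular formats.

All delimited text is comma-separated with a header row; missing values are
empty fields.  Lek-count tables carry columns ``lek_id, region_id, year,
count``; encounter histories carry ``unit_id, site_id, interval_start_doy,
interval_end_doy, exposure_days, outcome, stage`` plus covariate columns.
Day-of-year is 1-based (Jan 1 = 1), intervals are closed on both ends, and
``exposure_days = interval_end_doy - interval_start_doy``.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .diagnostics import SUMMARY_COLUMNS

__all__ = [
    "SchemaError",
    "ValidationError",
    "read_lek_counts",
    "filter_sparse_leks",
    "read_encounter_histories",
    "write_lek_counts",
    "write_encounter_histories",
    "write_posterior_summary",
    "read_posterior_summary",
    "ADULT_DOY_RANGE",
]

logger = logging.getLogger("lekdemog")

LEK_COLUMNS = ["lek_id", "region_id", "year", "count"]
HISTORY_COLUMNS = [
    "unit_id", "site_id", "interval_start_doy", "interval_end_doy",
    "exposure_days", "outcome", "stage",
]
#: Adult encounter histories span mid-March through end of August.
ADULT_DOY_RANGE = (75, 242)


class SchemaError(ValueError):
    """A file does not match the expected column schema."""


class ValidationError(ValueError):
    """A file matches the schema but violates a data invariant."""


def _require_columns(frame: pd.DataFrame, required: list[str], what: str) -> None:
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise SchemaError(
            f"{what}: missing columns {missing}; expected at least {required}"
        )


def read_lek_counts(path: str | Path, fill_year_gaps: bool = True) -> pd.DataFrame:
    """Read and validate a lek-count table.

    Missing counts are preserved as NaN (never coerced to zero).  With
    ``fill_year_gaps`` each lek's year index is made contiguous by inserting
    missing-count rows, so downstream models see a regular time grid.
    """
    frame = pd.read_csv(path)
    return validate_lek_counts(frame, fill_year_gaps=fill_year_gaps,
                               source=str(path))


def validate_lek_counts(frame: pd.DataFrame, fill_year_gaps: bool = True,
                        source: str = "<frame>") -> pd.DataFrame:
    _require_columns(frame, LEK_COLUMNS, source)
    frame = frame.copy()
    frame["year"] = frame["year"].astype(int)
    frame["count"] = pd.to_numeric(frame["count"], errors="raise")

    neg = frame.index[frame["count"] < 0]
    if len(neg):
        raise ValidationError(
            f"{source}: negative count at row(s) {list(neg[:5])}")
    frac = frame["count"].dropna() % 1
    if (frac != 0).any():
        raise ValidationError(f"{source}: counts must be whole numbers")

    dup = frame.duplicated(subset=["lek_id", "year"])
    if dup.any():
        key = frame.loc[dup, ["lek_id", "year"]].iloc[0]
        raise ValidationError(
            f"{source}: duplicate (lek_id, year) = "
            f"({key['lek_id']}, {key['year']})")

    multi_region = frame.groupby("lek_id")["region_id"].nunique()
    bad = multi_region[multi_region > 1]
    if len(bad):
        raise ValidationError(
            f"{source}: lek(s) {list(bad.index[:5])} map to multiple regions")

    if fill_year_gaps:
        filled = []
        for lek_id, grp in frame.groupby("lek_id", sort=True):
            years = np.arange(grp["year"].min(), grp["year"].max() + 1)
            grp = grp.set_index("year").reindex(years)
            grp["lek_id"] = lek_id
            grp["region_id"] = grp["region_id"].ffill().bfill()
            filled.append(grp.rename_axis("year").reset_index())
        frame = pd.concat(filled, ignore_index=True)[LEK_COLUMNS]
    return frame.sort_values(["lek_id", "year"]).reset_index(drop=True)


def filter_sparse_leks(frame: pd.DataFrame, min_years: int = 5) -> pd.DataFrame:
    """Drop leks with fewer than ``min_years`` non-missing counts.

    The inclusion threshold is configurable; 5 observed years is the
    package default.  An empty result is a warning, not an error.
    """
    if min_years < 1:
        raise ValueError("min_years must be >= 1")
    observed = frame.dropna(subset=["count"]).groupby("lek_id")["count"].size()
    keep = set(observed[observed >= min_years].index)
    before = frame["lek_id"].nunique()
    out = frame[frame["lek_id"].isin(keep)].reset_index(drop=True)
    logger.info("filter_sparse_leks(min_years=%d): %d -> %d leks",
                min_years, before, len(keep))
    if not len(out):
        warnings.warn("no leks remain after sparsity filtering", stacklevel=2)
    return out


def read_encounter_histories(path: str | Path, stage: str) -> pd.DataFrame:
    """Read and validate encounter histories for one life stage.

    Exposure days are recomputed from the interval endpoints and
    cross-checked against the stated column.  Within each unit, intervals
    must be ordered and non-overlapping, and a failure (outcome 0)
    terminates the history.  Adult-stage day-of-year values must lie inside
    the reproductive-season window [75, 242].
    """
    frame = pd.read_csv(path)
    return validate_encounter_histories(frame, stage, source=str(path))


def validate_encounter_histories(frame: pd.DataFrame, stage: str,
                                 source: str = "<frame>") -> pd.DataFrame:
    if stage not in ("nest", "brood", "adult"):
        raise ValueError(f"unknown stage {stage!r}")
    _require_columns(frame, HISTORY_COLUMNS, source)
    frame = frame.copy()
    if (frame["stage"] != stage).any():
        raise ValidationError(f"{source}: stage column must be {stage!r} for "
                              "all rows")
    if not frame["outcome"].isin([0, 1]).all():
        raise ValidationError(f"{source}: outcome must be 0 or 1")

    recomputed = frame["interval_end_doy"] - frame["interval_start_doy"]
    mismatch = frame.index[recomputed != frame["exposure_days"]]
    if len(mismatch):
        raise ValidationError(
            f"{source}: exposure_days disagrees with interval endpoints at "
            f"row(s) {list(mismatch[:5])}")
    if (frame["exposure_days"] < 1).any():
        raise ValidationError(f"{source}: exposure_days must be >= 1")

    if stage == "adult":
        lo, hi = ADULT_DOY_RANGE
        out_of_window = frame.index[(frame["interval_start_doy"] < lo)
                                    | (frame["interval_end_doy"] > hi)]
        if len(out_of_window):
            raise ValidationError(
                f"{source}: adult interval outside day-of-year window "
                f"[{lo}, {hi}] at row(s) {list(out_of_window[:5])}")

    frame = frame.sort_values(["unit_id", "interval_start_doy"],
                              kind="stable").reset_index(drop=True)
    for unit_id, grp in frame.groupby("unit_id", sort=False):
        starts = grp["interval_start_doy"].to_numpy()
        ends = grp["interval_end_doy"].to_numpy()
        if np.any(starts[1:] < ends[:-1]):
            raise ValidationError(
                f"{source}: unit {unit_id!r} has overlapping intervals")
        fates = grp["outcome"].to_numpy()
        zero = np.flatnonzero(fates == 0)
        if len(zero) > 1 or (len(zero) == 1 and zero[0] != len(fates) - 1):
            raise ValidationError(
                f"{source}: unit {unit_id!r} has intervals after a failure "
                "(outcome 0 must terminate the history)")
    return frame


def write_lek_counts(frame: pd.DataFrame, path: str | Path) -> None:
    """Write a lek-count table (empty fields mark missing counts)."""
    frame.to_csv(path, index=False)


def write_encounter_histories(frame: pd.DataFrame, path: str | Path) -> None:
    frame.to_csv(path, index=False)


def write_posterior_summary(summary: pd.DataFrame, path: str | Path,
                            float_format: str = "%.6g") -> None:
    """Write a posterior summary with the deterministic column order
    ``parameter, mean, sd, q2.5, q50, q97.5, rhat, pd``."""
    missing = [c for c in SUMMARY_COLUMNS if c not in summary.columns]
    if missing:
        raise SchemaError(f"summary lacks columns {missing}")
    summary[SUMMARY_COLUMNS].to_csv(path, index=False,
                                    float_format=float_format)


def read_posterior_summary(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    _require_columns(frame, SUMMARY_COLUMNS, str(path))
    return frame[SUMMARY_COLUMNS]
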