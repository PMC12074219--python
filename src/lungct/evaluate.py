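"""Grouped stage-wise statistics and report exports.

Per-scan standardized results are flattened into a tidy long DataFrame
(one row per scan x material x stage) which the summary operations
aggregate: mean +/- SD per protocol group, SD-reduction ratios between
the raw and standardized stages, and Tukey boxplot statistics.
"""
from __future__ import annotations

import logging
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd

from .io import RawMeasurement
from .phantom import PhantomDefinition
from .standardize import CalibrationModel, StandardizedResult, standardize_scan

__all__ = [
    "STAGES",
    "GroupSummary",
    "results_to_frame",
    "standardize_measurements",
    "summarize",
    "reduction_report",
    "boxplot_export",
]

logger = logging.getLogger("lungct")

#: Pipeline stages in order.
STAGES = ("raw", "internal_cal", "standardized")

GROUP_KEYS = ("scanner", "ctdi_mgy", "kvp", "recon", "basis")


class GroupSummary(NamedTuple):
    """Mean +/- SD of a material's CT number at one stage in one group."""

    group: dict
    material: str
    stage: str
    mean: float
    sd: float
    n: int


def results_to_frame(
    records: Iterable[
        tuple[RawMeasurement, CalibrationModel, list[StandardizedResult]]
    ],
) -> pd.DataFrame:
    """Flatten per-scan results into the long results table.

    Columns: scanner, vendor, kvp, ctdi_mgy, recon, basis, flagged,
    material, stage, hu.
    """
    rows = []
    for measured, model, results in records:
        p = measured.protocol
        for res in results:
            for stage in STAGES:
                rows.append(
                    {
                        "scanner": p.scanner_id,
                        "vendor": p.vendor,
                        "kvp": p.kvp,
                        "ctdi_mgy": p.ctdi,
                        "recon": p.recon,
                        "basis": model.basis,
                        "flagged": model.flagged,
                        "material": res.target_name,
                        "stage": stage,
                        "hu": res.stage_values[stage],
                    }
                )
    return pd.DataFrame(rows)


def standardize_measurements(
    measurements: Iterable[RawMeasurement],
    phantom: PhantomDefinition,
    alpha_mode: str = "wls",
) -> tuple[pd.DataFrame, list[CalibrationModel]]:
    """Standardize a batch of measurements into the long results table."""
    records, models = [], []
    for m in measurements:
        model, results = standardize_scan(m, phantom, alpha_mode=alpha_mode)
        records.append((m, model, results))
        models.append(model)
    return results_to_frame(records), models


def _check_results_frame(results: pd.DataFrame) -> None:
    if results.empty:
        raise ValueError("results table is empty")
    missing = {"material", "stage", "hu"} - set(results.columns)
    if missing:
        raise ValueError(f"results table missing columns: {sorted(missing)}")


def summarize(
    results: pd.DataFrame,
    group_by: list[str] | None = None,
    exclude_flagged: bool = True,
) -> pd.DataFrame:
    """Sample mean and SD (n-1 denominator) per group x material x stage.

    Rows are ordered deterministically: sorted group keys and material,
    stages in pipeline order.  Scans flagged during calibration are
    excluded by default; the per-group count of exclusions is reported
    in ``n_excluded``.
    """
    _check_results_frame(results)
    group_by = list(group_by or [])
    unknown = [k for k in group_by if k not in results.columns]
    if unknown:
        raise ValueError(f"unknown group keys: {unknown}")
    df = results.copy()
    if "flagged" not in df.columns:
        df["flagged"] = False
    keys = group_by + ["material", "stage"]
    rows = []
    for key_vals, sub in df.groupby(keys, sort=True):
        if not isinstance(key_vals, tuple):
            key_vals = (key_vals,)
        kept = sub[~sub["flagged"]]
        n_excluded = int(sub["flagged"].sum())
        if kept.empty:
            logger.warning("group %s fully excluded by flags", dict(zip(keys, key_vals)))
            continue
        values = kept["hu"].to_numpy(dtype=float)
        n = values.size
        if n == 1:
            logger.warning("group %s has a single scan; SD reported as 0",
                           dict(zip(keys, key_vals)))
            sd = 0.0
        else:
            sd = float(values.std(ddof=1))
        row = dict(zip(keys, key_vals))
        row.update(
            mean=float(values.mean()), sd=sd, n=n, n_excluded=n_excluded
        )
        rows.append(row)
    out = pd.DataFrame(rows)
    out["stage"] = pd.Categorical(out["stage"], categories=STAGES, ordered=True)
    sort_cols = group_by + ["material", "stage"]
    return out.sort_values(sort_cols, kind="mergesort").reset_index(drop=True)


def reduction_report(summaries: pd.DataFrame) -> pd.DataFrame:
    """SD-reduction ratios (standardized vs raw) per group and material.

    A ratio >= 1 means standardization failed to reduce spread in that
    group and is flagged; groups with zero raw SD report an undefined
    (NaN) ratio.
    """
    needed = {"material", "stage", "sd"}
    if not needed <= set(summaries.columns):
        raise ValueError(f"summary table missing columns: {sorted(needed - set(summaries.columns))}")
    group_cols = [
        c
        for c in summaries.columns
        if c not in ("stage", "mean", "sd", "n", "n_excluded")
    ]
    wide = summaries.pivot_table(
        index=group_cols, columns="stage", values="sd", observed=True
    ).reset_index()
    if "raw" not in wide.columns or "standardized" not in wide.columns:
        raise ValueError("need both raw and standardized stages per group")
    out = wide.rename(columns={"raw": "sd_raw", "standardized": "sd_std"})
    if "internal_cal" in out.columns:
        out = out.rename(columns={"internal_cal": "sd_internal"})
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(
            out["sd_raw"].to_numpy() > 0,
            out["sd_std"].to_numpy() / out["sd_raw"].to_numpy(),
            np.nan,
        )
    out["ratio"] = ratio
    out["no_improvement"] = out["ratio"] >= 1.0
    out.columns.name = None
    return out


def boxplot_export(
    results: pd.DataFrame, group_by: list[str] | None = None
) -> pd.DataFrame:
    """Tukey boxplot statistics per material x stage x group.

    Quartiles use linear interpolation; whiskers extend to the most
    extreme points within 1.5 IQR of the box; points beyond are listed
    as outliers (semicolon-joined in the ``outliers`` column).
    """
    _check_results_frame(results)
    group_by = list(group_by or [])
    keys = group_by + ["material", "stage"]
    rows = []
    for key_vals, sub in results.groupby(keys, sort=True):
        if not isinstance(key_vals, tuple):
            key_vals = (key_vals,)
        v = np.sort(sub["hu"].to_numpy(dtype=float))
        q1, med, q3 = np.percentile(v, [25, 50, 75])
        iqr = q3 - q1
        lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
        inside = v[(v >= lo_fence) & (v <= hi_fence)]
        outliers = v[(v < lo_fence) | (v > hi_fence)]
        row = dict(zip(keys, key_vals))
        row.update(
            whisker_low=float(inside.min()),
            q1=float(q1),
            median=float(med),
            q3=float(q3),
            whisker_high=float(inside.max()),
            n=int(v.size),
            outliers=";".join(f"{x:.6g}" for x in outliers),
        )
        rows.append(row)
    out = pd.DataFrame(rows)
    out["stage"] = pd.Categorical(out["stage"], categories=STAGES, ordered=True)
    return out.sort_values(keys, kind="mergesort").reset_index(drop=True)
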