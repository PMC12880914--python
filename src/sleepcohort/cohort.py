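"""Night harmonization, validity screens and analysis-cohort selection.

Nights are labeled by the calendar date of final awakening; a night passes
the validity screen when every present device agrees it looks like a real
main sleep period (TST 3–16 h starting between 19:00 and 07:00, WASO at
most 3 h, EEG quality above 30/100 when reported, SOL at most 120 min when
defined). Children enter the analysis cohort with at least three nights
that are simultaneously valid on all required sources.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date
from itertools import combinations
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .dtypes import NightMetrics
from .timeutils import minutes_since_noon

# Screen thresholds (minutes on the noon-anchored axis unless noted).
TST_MIN = 180.0          # 3 h
TST_MAX = 960.0          # 16 h
SO_EARLIEST = 420.0      # 19:00 -> 420 min after noon
SO_LATEST = 1140.0       # 07:00 -> 1140 min after noon
WASO_MAX = 180.0         # 3 h
QUALITY_MIN = 30.0       # quality score must exceed this
SOL_MAX = 120.0          # longer onset latencies are outliers


@dataclass(frozen=True)
class ValidityThresholds:
    tst_min: float = TST_MIN
    tst_max: float = TST_MAX
    so_earliest: float = SO_EARLIEST
    so_latest: float = SO_LATEST
    waso_max: float = WASO_MAX
    quality_min: float = QUALITY_MIN
    sol_max: float = SOL_MAX


DEFAULT_THRESHOLDS = ValidityThresholds()


def assign_night_date(metrics: NightMetrics) -> date:
    """The night label: the local calendar date of final awakening."""
    return metrics.fa.date()


def screen_gross_duration(metrics: NightMetrics,
                          th: ValidityThresholds = DEFAULT_THRESHOLDS) -> bool:
    """Gross screen applied at harmonization: 3 h <= TST <= 16 h, inclusive."""
    return th.tst_min <= metrics.tst_min <= th.tst_max


def night_validity_reasons(metrics: NightMetrics,
                           th: ValidityThresholds = DEFAULT_THRESHOLDS
                           ) -> list[str]:
    """Per-criterion failures for one device-night (empty = valid).

    The "started between 7pm and 7am" clause is applied to the sleep-onset
    clock time, inclusive at both bounds, on the noon-anchored axis.
    """
    reasons = []
    if not (th.tst_min <= metrics.tst_min <= th.tst_max):
        reasons.append("TST outside 3-16 h")
    so_m = minutes_since_noon(metrics.so)
    if not (th.so_earliest <= so_m <= th.so_latest):
        reasons.append("SO outside 19:00-07:00")
    if metrics.waso_min > th.waso_max:
        reasons.append("WASO > 3 h")
    if metrics.quality_score is not None and metrics.quality_score <= th.quality_min:
        reasons.append("quality score <= 30")
    if metrics.sol_min is not None and metrics.sol_min > th.sol_max:
        reasons.append("SOL > 120 min (outlier)")
    if not metrics.usable:
        reasons.append("excess missing epochs")
    return reasons


def is_valid_night(metrics: NightMetrics,
                   th: ValidityThresholds = DEFAULT_THRESHOLDS) -> bool:
    return not night_validity_reasons(metrics, th)


# ---------------------------------------------------------------------------
# Long-format cohort table
# ---------------------------------------------------------------------------

METRIC_COLUMNS = ["so_noon_min", "fa_noon_min", "waso_min", "tst_min", "sol_min"]


def metrics_to_frame(metrics: Iterable[NightMetrics],
                     roster: Optional[pd.DataFrame] = None,
                     th: ValidityThresholds = DEFAULT_THRESHOLDS
                     ) -> pd.DataFrame:
    """Long table: one row per child x night x source, with validity flags.

    SO/FA are stored as minutes since the night's anchor noon so that
    averaging and concordance are well defined across midnight.
    """
    rows = []
    for m in metrics:
        night = assign_night_date(m)
        from .timeutils import noon_minutes_of
        reasons = night_validity_reasons(m, th)
        rows.append({
            "child_id": m.child_id,
            "night_date": night.isoformat(),
            "source": m.device,
            "dialect": m.dialect,
            "so_noon_min": noon_minutes_of(m.so, night),
            "fa_noon_min": noon_minutes_of(m.fa, night),
            "waso_min": m.waso_min,
            "tst_min": m.tst_min,
            "sol_min": m.sol_min,
            "quality_score": m.quality_score,
            "valid": not reasons,
            "invalid_reasons": ";".join(reasons),
        })
    df = pd.DataFrame(rows)
    if df.empty:
        df = pd.DataFrame(columns=["child_id", "night_date", "source",
                                   "dialect", *METRIC_COLUMNS,
                                   "quality_score", "valid", "invalid_reasons"])
    # two episodes may share a final-awakening date (e.g. an early-evening
    # nap ending the same day); keep_main_sleep_period resolves them
    if roster is not None:
        df = df.merge(roster[["child_id", "family_id", "diagnosis", "age", "sex"]],
                      on="child_id", how="left")
    return df


def keep_main_sleep_period(df: pd.DataFrame) -> pd.DataFrame:
    """One record per (child, night, source): keep the longest-TST episode."""
    out = (df.sort_values(["tst_min", "so_noon_min"],
                          ascending=[False, True], kind="mergesort")
             .drop_duplicates(["child_id", "night_date", "source", "dialect"])
             .sort_values(["child_id", "night_date", "source"])
             .reset_index(drop=True))
    assert not out.duplicated(["child_id", "night_date", "source"]).any()
    return out


def select_analysis_cohort(table: pd.DataFrame, min_valid_nights: int = 3,
                           required_sources: Optional[list[str]] = None,
                           ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Retain children with >= min_valid_nights nights valid on all sources.

    A night counts only when every required source is present and valid on
    that night; only those simultaneously-valid nights are retained for the
    retained children. Returns (selected table, per-group counts).
    Idempotent: reapplying the selection changes nothing.
    """
    if required_sources is None:
        required_sources = sorted(table["source"].unique())
    sub = table[table["source"].isin(required_sources)]
    ok = (sub.groupby(["child_id", "night_date"])
             .agg(n_valid=("valid", "sum"), n_src=("source", "nunique"))
             .reset_index())
    ok = ok[(ok["n_src"] == len(required_sources))
            & (ok["n_valid"] == ok["n_src"])][["child_id", "night_date"]]
    merged = table.merge(ok, on=["child_id", "night_date"])
    counts = ok.groupby("child_id").size()
    keep = counts[counts >= min_valid_nights].index
    selected = merged[merged["child_id"].isin(keep)].reset_index(drop=True)
    if "diagnosis" in selected.columns:
        group_counts = (selected.drop_duplicates("child_id")
                        .groupby("diagnosis").size().rename("n_children")
                        .reset_index())
    else:
        group_counts = pd.DataFrame({"diagnosis": [], "n_children": []})
    return selected, group_counts


def device_night_overlap(table: pd.DataFrame,
                         devices: Optional[list[str]] = None) -> dict:
    """Venn decomposition of device coverage over (child, night) pairs.

    Counts nights passing the gross-duration screen per device; cells are
    keyed by sorted device subsets ("watch", "watch+mat", ...). The cell
    sum equals the number of distinct nights with at least one device.
    """
    if devices is None:
        devices = sorted(table["source"].unique())
    passing = table[table["source"].isin(devices)
                    & table["tst_min"].between(TST_MIN, TST_MAX)]
    per_night = (passing.groupby(["child_id", "night_date"])["source"]
                 .agg(lambda s: tuple(sorted(set(s)))))
    cells = {}
    for r in range(1, len(devices) + 1):
        for combo in combinations(sorted(devices), r):
            cells["+".join(combo)] = 0
    for combo in per_night:
        cells["+".join(combo)] += 1
    return {
        "cells": cells,
        "n_nights_any": int(per_night.shape[0]),
        "n_device_nights": int(passing.shape[0]),
        "per_device": {d: int((passing["source"] == d).sum()) for d in devices},
    }


def average_per_child(table: pd.DataFrame, measure: str) -> pd.DataFrame:
    """Per-child arithmetic mean of a measure over included nights, by source.

    Clock-time measures are already on the noon-anchored minute axis in the
    long table, so a plain mean is the circular-safe mean.
    """
    if measure not in table.columns:
        raise KeyError(f"unknown measure {measure!r}")
    return (table.dropna(subset=[measure])
            .groupby(["child_id", "source"], as_index=False)[measure]
            .mean())
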