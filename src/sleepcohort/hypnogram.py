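"""Per-night sleep metrics from epoch-level label series.

Implements the device-dialect rules used to harmonize heterogeneous
recordings onto a single set of nightly measures:

* **SO** (sleep onset): start of the first run of consolidated sleep, i.e.
  the first sleep epoch opening a run of at least ``consolidation_min``
  (default 10) minutes of consecutive sleep.
* **FA** (final awakening): the first wake epoch after the night's last
  consolidated sleep run, required to be followed by at least
  ``fa_wake_min`` (default 120) minutes of recording containing no further
  consolidated sleep — or by the end of the recording, for dialects that
  accept a truncated tail (``fa_end_of_recording_ok``). Measuring the tail
  as "time free of consolidated sleep" rather than one uninterrupted wake
  run keeps the rule robust to isolated misclassified epochs.
* **WASO**: total wake minutes strictly inside [SO, FA), optionally
  excluding brief wake runs of at most ``brief_wake_exclusion_min`` minutes
  (5 for the smartwatch dialect, whose classifier over-calls brief
  awakenings; 0 for the EEG dialects).
* **TST** = (FA − SO) − WASO; **SOL** = SO − recording start.

The brief-wake exclusion applies only to the WASO sum; SO/FA segmentation
always runs on the raw labels. MISSING epochs count as wake for
segmentation, and a night whose [SO, FA) span is more than 10% MISSING is
flagged unusable.
"""

from __future__ import annotations

from dataclasses import replace
from datetime import date, datetime, time, timedelta
from typing import Optional, Sequence, Tuple

import numpy as np

from .dtypes import (
    BINARY_LABELS,
    MISSING,
    SLEEP,
    STAGE_PRIORITY,
    STAGES,
    WAKE,
    EpochSeries,
    NightMetrics,
    NoFinalAwakeningError,
    NoSleepOnsetError,
    RuleDialect,
)
from .timeutils import mean_clock_time, minutes_since_noon, night_datetime

SOL_OUTLIER_MIN = 120.0  # nights with longer onset latency are flagged


# ---------------------------------------------------------------------------
# Stage handling
# ---------------------------------------------------------------------------

def binarize_stages(series: EpochSeries) -> EpochSeries:
    """Collapse staged labels to SLEEP/WAKE (W -> WAKE, any sleep stage -> SLEEP).

    MISSING is preserved. Multi-channel input must first go through
    :func:`majority_vote`.
    """
    if series.is_multichannel:
        raise ValueError("binarize_stages expects a single-channel series; "
                         "apply majority_vote first")
    out = np.empty(series.n_epochs, dtype=object)
    for i, lab in enumerate(series.labels):
        if lab == MISSING:
            out[i] = MISSING
        elif lab == "W":
            out[i] = WAKE
        elif lab in STAGES:
            out[i] = SLEEP
        elif lab in (SLEEP, WAKE):
            out[i] = lab  # already binary: pass through
        else:
            raise ValueError(f"unknown stage label {lab!r} at epoch {i}")
    return replace(series, labels=out, confidence=None)


def majority_vote(series: EpochSeries) -> EpochSeries:
    """Reduce a multi-channel staged series to one stage per epoch.

    Per epoch the modal stage across non-missing channels wins; ties are
    broken by the highest summed confidence, then by the fixed stage order
    W > N1 > N2 > N3 > REM. An epoch missing on every channel stays MISSING.
    Single-channel input is returned unchanged.
    """
    if not series.is_multichannel:
        return series
    n_ch, n_ep = series.labels.shape
    conf = series.confidence
    if conf is None:
        conf = np.ones_like(series.labels, dtype=float)
    out = np.empty(n_ep, dtype=object)
    for i in range(n_ep):
        votes: dict = {}
        for c in range(n_ch):
            lab = series.labels[c, i]
            if lab == MISSING:
                continue
            if lab not in STAGE_PRIORITY:
                raise ValueError(f"unknown stage label {lab!r} in channel {c}")
            cnt, csum = votes.get(lab, (0, 0.0))
            votes[lab] = (cnt + 1, csum + float(conf[c, i]))
        if not votes:
            out[i] = MISSING
            continue
        # sort: most votes, then highest confidence sum, then stage priority
        out[i] = min(
            votes.items(),
            key=lambda kv: (-kv[1][0], -kv[1][1], STAGE_PRIORITY[kv[0]]),
        )[0]
    return replace(series, labels=out, confidence=None)


# ---------------------------------------------------------------------------
# Run segmentation
# ---------------------------------------------------------------------------

def _runs(labels: np.ndarray) -> list[tuple[str, int, int]]:
    """Run-length encode labels as (label, start, length) triples."""
    runs = []
    start = 0
    for i in range(1, len(labels) + 1):
        if i == len(labels) or labels[i] != labels[start]:
            runs.append((labels[start], start, i - start))
            start = i
    return runs


def _as_wake_for_segmentation(labels: np.ndarray) -> np.ndarray:
    """MISSING counts as wake when locating SO/FA."""
    return np.array([WAKE if l == MISSING else l for l in labels], dtype=object)


def _locate_so_fa(labels: np.ndarray, epoch_s: int,
                  dialect: RuleDialect) -> Tuple[int, int]:
    """Return (so_epoch, fa_epoch) indices; fa may equal len(labels)."""
    seg = _as_wake_for_segmentation(labels)
    epm = epoch_s / 60.0  # minutes per epoch
    runs = _runs(seg)
    sleep_runs = [(s, l) for lab, s, l in runs if lab == SLEEP]
    qualifying = [(s, l) for s, l in sleep_runs if l * epm >= dialect.consolidation_min]
    if not qualifying:
        raise NoSleepOnsetError("no sleep onset: no consolidated sleep run of "
                                f">= {dialect.consolidation_min} min")
    so = qualifying[0][0]

    n = len(seg)
    # FA follows the last consolidated sleep run. After it no consolidated
    # sleep exists, so the remainder of the recording is the wake tail
    # (isolated mislabeled sleep epochs do not reset it); the tail must
    # last >= fa_wake_min unless the dialect accepts end-of-recording.
    s, l = qualifying[-1]
    fa = s + l  # first epoch after the run (may equal n: end of recording)
    tail_min = (n - fa) * epm
    if tail_min < dialect.fa_wake_min and not dialect.fa_end_of_recording_ok:
        raise NoFinalAwakeningError(
            "no final awakening: last consolidated sleep run followed by "
            f"only {tail_min:.0f} min of recording "
            f"(< {dialect.fa_wake_min:.0f} min of wake required)")
    return so, fa


def _waso_minutes(labels: np.ndarray, so: int, fa: int, epoch_s: int,
                  exclusion_min: float) -> float:
    """Sum wake-run minutes in [so, fa), dropping runs <= exclusion_min."""
    seg = _as_wake_for_segmentation(labels[so:fa])
    epm = epoch_s / 60.0
    total = 0.0
    for lab, _s, l in _runs(seg):
        if lab == WAKE and l * epm > exclusion_min:
            total += l * epm
    return total


def extract_metrics(series: EpochSeries, dialect: RuleDialect,
                    quality_score: Optional[float] = None) -> NightMetrics:
    """Derive NightMetrics from a single-channel SLEEP/WAKE series.

    Raises :class:`NoSleepOnsetError` / :class:`NoFinalAwakeningError` for
    nights with no qualifying onset or awakening; both mark an unusable
    night rather than a software fault.
    """
    if series.is_multichannel:
        raise ValueError("extract_metrics expects a single-channel series")
    labels = series.labels
    bad = set(labels) - set(BINARY_LABELS)
    if bad:
        raise ValueError(f"non-binary labels {sorted(map(str, bad))}; "
                         "binarize staged input first")
    so_i, fa_i = _locate_so_fa(labels, series.epoch_s, dialect)
    waso = _waso_minutes(labels, so_i, fa_i, series.epoch_s,
                         dialect.brief_wake_exclusion_min)
    epm = series.epoch_s / 60.0
    span = (fa_i - so_i) * epm
    tst = span - waso
    sol = so_i * epm  # recording start is the lights-off proxy

    n_missing = int(np.sum(labels[so_i:fa_i] == MISSING))
    missing_frac = n_missing / max(fa_i - so_i, 1)

    return NightMetrics(
        child_id=series.child_id,
        night_date=series.night_date,
        device=series.device,
        dialect=dialect.name,
        so=series.epoch_time(so_i),
        fa=series.epoch_time(fa_i),
        waso_min=waso,
        tst_min=tst,
        sol_min=sol,
        sol_outlier=sol > SOL_OUTLIER_MIN,
        quality_score=quality_score,
        missing_frac=missing_frac,
        usable=missing_frac <= dialect.max_missing_frac,
    )


def compute_sol(so: datetime, recording_start: datetime) -> tuple[float, bool]:
    """Sleep-onset latency in minutes and its >120-min outlier flag."""
    sol = (so - recording_start).total_seconds() / 60.0
    if sol < 0:
        raise ValueError("sleep onset precedes recording start")
    return sol, sol > SOL_OUTLIER_MIN


# ---------------------------------------------------------------------------
# Parent-report equivalents
# ---------------------------------------------------------------------------

def diary_metrics(child_id: str, night: date, so: time, fa: time,
                  waso_min: float, source: str = "diary") -> NightMetrics:
    """Nightly metrics from a parent diary entry (reported SO/FA/WASO).

    Times are interpreted on the noon-anchored axis of the labeled night:
    an onset after midnight belongs to the morning of the final-awakening
    date. TST = (FA − SO) − WASO.
    """
    if waso_min < 0:
        raise ValueError("negative reported WASO")
    so_m = minutes_since_noon(so)
    fa_m = minutes_since_noon(fa)
    if fa_m <= so_m:
        raise ValueError(f"reported FA ({fa}) not after SO ({so}) on the "
                         "noon-anchored night axis")
    span = fa_m - so_m
    if waso_min > span:
        raise ValueError("reported WASO exceeds the SO-FA span")
    return NightMetrics(
        child_id=child_id,
        night_date=night,
        device=source,
        dialect=source,
        so=night_datetime(night, so_m),
        fa=night_datetime(night, fa_m),
        waso_min=float(waso_min),
        tst_min=span - float(waso_min),
        sol_min=None,
    )


def cshq_metrics(child_id: str, weekday_so: time, weekday_fa: time,
                 weekend_so: time, weekend_fa: time,
                 waso_min: float) -> NightMetrics:
    """Typical-night metrics from questionnaire items.

    SO and FA are each averaged across the weekday and weekend reports on
    the noon-anchored axis before TST = (FA − SO) − WASO is computed; WASO
    is reported once, regardless of day type.
    """
    for name, v in (("weekday_so", weekday_so), ("weekday_fa", weekday_fa),
                    ("weekend_so", weekend_so), ("weekend_fa", weekend_fa),
                    ("waso_min", waso_min)):
        if v is None:
            raise ValueError(f"missing questionnaire field {name}")
    so = mean_clock_time([weekday_so, weekend_so])
    fa = mean_clock_time([weekday_fa, weekend_fa])
    return diary_metrics(child_id, date(2000, 1, 1), so, fa, waso_min,
                         source="cshq")
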