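"""Core domain containers shared across the pipeline.

Conventions used throughout:

* Epochs are half-open intervals ``[start + i*epoch_s, start + (i+1)*epoch_s)``,
  0-based.
* All clock times attached to a night live on a *noon-anchored* axis
  (minutes since noon of the evening the night began), which removes
  midnight-wraparound sign errors when averaging or comparing onset times.
* Durations (WASO, TST, SOL) are minutes, derived from elapsed epoch counts,
  never from wall-clock subtraction, so they are immune to DST transitions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import date, datetime
from typing import Optional, Sequence

import numpy as np

# Single-channel binary labels
SLEEP = "SLEEP"
WAKE = "WAKE"
MISSING = "MISSING"
BINARY_LABELS = (SLEEP, WAKE, MISSING)

# Staged labels (multi-channel EEG dialects). Fixed priority order used for
# deterministic tie-breaking in the majority vote: W > N1 > N2 > N3 > REM.
STAGES = ("W", "N1", "N2", "N3", "REM")
STAGE_PRIORITY = {s: i for i, s in enumerate(STAGES)}


@dataclass
class EpochSeries:
    """One night's per-epoch labels from one device.

    ``labels`` is a 1-D object/str array for single-channel series over
    {SLEEP, WAKE, MISSING}, or a 2-D (n_channels, n_epochs) array of stage
    labels over {W, N1, N2, N3, REM, MISSING} with a matching ``confidence``
    array in [0, 1] for multi-channel series.
    """

    child_id: str
    night_date: date
    device: str
    recording_start: datetime
    epoch_s: int
    labels: np.ndarray
    confidence: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=object)
        if self.labels.size == 0:
            raise ValueError("EpochSeries requires at least one epoch")
        if self.epoch_s not in (30, 60):
            raise ValueError(f"epoch_s must be 30 or 60 s, got {self.epoch_s}")
        if self.confidence is not None:
            self.confidence = np.asarray(self.confidence, dtype=float)
            if self.confidence.shape != self.labels.shape:
                raise ValueError("confidence shape must match labels shape")
            if np.any((self.confidence < 0) | (self.confidence > 1)):
                raise ValueError("confidences must lie in [0, 1]")

    @property
    def n_epochs(self) -> int:
        return self.labels.shape[-1]

    @property
    def n_channels(self) -> int:
        return 1 if self.labels.ndim == 1 else self.labels.shape[0]

    @property
    def is_multichannel(self) -> bool:
        return self.labels.ndim == 2

    @property
    def duration_min(self) -> float:
        return self.n_epochs * self.epoch_s / 60.0

    def epoch_time(self, i: int) -> datetime:
        """Wall-clock start of epoch ``i`` (i may equal n_epochs: end of rec)."""
        from datetime import timedelta

        return self.recording_start + timedelta(seconds=i * self.epoch_s)


@dataclass(frozen=True)
class RuleDialect:
    """Device-specific thresholds for deriving SO/FA/WASO from labels.

    ``embrace``   — smartwatch actigraphy dialect: 5-min brief-wake exclusion
                    when summing WASO, full 2-h wake required after FA.
    ``eeg_algo``  — headband's own staging dialect: no exclusion.
    ``eeg_external`` — external automatic stager dialect: no exclusion,
                    end-of-recording accepted in place of the 2-h wake tail.
    """

    name: str
    consolidation_min: float = 10.0
    fa_wake_min: float = 120.0
    brief_wake_exclusion_min: float = 0.0
    fa_end_of_recording_ok: bool = False
    max_missing_frac: float = 0.10

    def __post_init__(self) -> None:
        if self.consolidation_min <= 0:
            raise ValueError("consolidation_min must be > 0")
        if self.brief_wake_exclusion_min < 0:
            raise ValueError("brief_wake_exclusion_min must be >= 0")


EMBRACE = RuleDialect(name="embrace", brief_wake_exclusion_min=5.0)
EEG_ALGO = RuleDialect(name="eeg_algo")
EEG_EXTERNAL = RuleDialect(name="eeg_external", fa_end_of_recording_ok=True)

DIALECTS = {d.name: d for d in (EMBRACE, EEG_ALGO, EEG_EXTERNAL)}


class NoSleepOnsetError(ValueError):
    """Raised when no consolidated sleep run exists (unusable night)."""


class NoFinalAwakeningError(ValueError):
    """Raised when no qualifying final awakening exists (unusable night)."""


@dataclass
class NightMetrics:
    """Derived per-night summary: SO, FA, WASO, TST, SOL plus provenance.

    Invariant: ``TST == (FA - SO) - WASO`` exactly, in minutes, and all
    quantities are non-negative.
    """

    child_id: str
    night_date: date
    device: str
    dialect: str
    so: datetime
    fa: datetime
    waso_min: float
    tst_min: float
    sol_min: Optional[float] = None
    sol_outlier: bool = False
    quality_score: Optional[float] = None
    missing_frac: float = 0.0
    usable: bool = True

    @property
    def span_min(self) -> float:
        return self.tst_min + self.waso_min


@dataclass
class AgreementResult:
    """Pairwise concordance between two sources of one sleep measure."""

    measure: str
    source_a: str
    source_b: str
    ccc: float
    pearson_r: float
    n: int
    p_value: Optional[float] = None
    n_iterations: Optional[int] = None
    significant: Optional[bool] = None


@dataclass
class MixedModelResult:
    """Family random-intercept linear mixed model summary."""

    outcome: str
    params: dict          # fixed-effect name -> beta
    bse: dict             # fixed-effect name -> SE
    pvalues: dict         # fixed-effect name -> p
    sigma2_between: float  # family random-intercept variance
    sigma2_within: float   # residual variance
    icc: float
    f2_diagnosis: Optional[float]
    n_obs: int
    n_groups: int
    converged: bool
    marginal_r2: float = float("nan")
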