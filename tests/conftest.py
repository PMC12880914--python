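"""Shared fixtures and the independent brute-force extraction oracle."""

from __future__ import annotations

from datetime import date, datetime
from itertools import groupby

import numpy as np
import pytest

from sleepcohort.dtypes import MISSING, SLEEP, WAKE, EpochSeries


def make_series(labels, epoch_s=60, child="C1", night=date(2023, 5, 3),
                device="watch", start=datetime(2023, 5, 2, 22, 0)):
    return EpochSeries(child_id=child, night_date=night, device=device,
                       recording_start=start, epoch_s=epoch_s,
                       labels=np.array(labels, dtype=object))


def expand(spec: list[tuple[str, int]]) -> list[str]:
    """[('W', 15), ('S', 3), ...] -> label list (S=SLEEP, W=WAKE, M=MISSING)."""
    m = {"S": SLEEP, "W": WAKE, "M": MISSING}
    out = []
    for sym, n in spec:
        out.extend([m[sym]] * n)
    return out


# Worked example: W*15 S*3 W*2 S*30 W*4 S*60 W*7 S*30 W*130, 1-min epochs.
WORKED_EXAMPLE = [("W", 15), ("S", 3), ("W", 2), ("S", 30), ("W", 4),
                  ("S", 60), ("W", 7), ("S", 30), ("W", 130)]


def oracle_extract(labels, epoch_s, consolidation_min=10.0, fa_wake_min=120.0,
                   brief_wake_exclusion_min=0.0, fa_end_of_recording_ok=False):
    """Independent brute-force oracle: enumerate every run explicitly.

    Returns (so_epoch, fa_epoch, waso_min, tst_min) or raises ValueError
    with 'no sleep onset' / 'no final awakening'. MISSING counts as wake.
    Deliberately written with groupby + explicit loops, sharing no code
    with the implementation under test.
    """
    epm = epoch_s / 60.0
    seg = [WAKE if l == MISSING else l for l in labels]
    runs = []  # (label, start, length)
    i = 0
    for lab, grp in groupby(seg):
        n = len(list(grp))
        runs.append((lab, i, n))
        i += n

    consolidated = [(s, n) for lab, s, n in runs
                    if lab == SLEEP and n * epm >= consolidation_min]
    if not consolidated:
        raise ValueError("no sleep onset")
    so = consolidated[0][0]

    last_start, last_len = consolidated[-1]
    fa = last_start + last_len
    tail_min = (len(seg) - fa) * epm
    if tail_min < fa_wake_min and not fa_end_of_recording_ok:
        raise ValueError("no final awakening")

    waso = 0.0
    for lab, s, n in runs:
        if (lab == WAKE and s >= so and s + n <= fa
                and n * epm > brief_wake_exclusion_min):
            waso += n * epm
    tst = (fa - so) * epm - waso
    return so, fa, waso, tst


@pytest.fixture(scope="session")
def small_cohort():
    """A modest noisy cohort shared by the slower integration tests."""
    from sleepcohort.simulate import CohortSpec, simulate_cohort

    spec = CohortSpec(n_families=12, nights_min=6, nights_max=10, seed=42)
    roster, truth, recordings, diary, behavior, truths = simulate_cohort(spec)
    return dict(spec=spec, roster=roster, truth=truth, recordings=recordings,
                diary=diary, behavior=behavior, truths=truths)


@pytest.fixture(scope="session")
def noiseless_cohort():
    """All observation noise zeroed: extracted metrics must equal truth."""
    from sleepcohort.simulate import CohortSpec, DeviceModel, simulate_cohort

    devices = (
        DeviceModel(name="watch", epoch_s=60),
        DeviceModel(name="mat", epoch_s=60),
        DeviceModel(name="eeg", epoch_s=30, n_channels=4, staged=True),
    )
    spec = CohortSpec(n_families=6, nights_min=4, nights_max=6,
                      device_models=devices, diary_bias=0.0, diary_sd=0.0,
                      seed=99)
    roster, truth, recordings, diary, behavior, truths = simulate_cohort(spec)
    return dict(spec=spec, roster=roster, truth=truth, recordings=recordings,
                diary=diary, behavior=behavior, truths=truths)
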