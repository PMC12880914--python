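"""Synthetic family-paired sleep cohort with known ground truth.

Emulates the statistical structure of a multi-device home-sleep study of
autistic children and their non-autistic siblings: one child of each per
family, a couple of weeks of nights per child, three noisy observation
channels per night (a smartwatch whose classifier over-calls brief
awakenings, a mattress sensor, and a multi-channel EEG headband), a biased
parent diary, and behavior questionnaire scores whose liability is
correlated with the child's latent sleep-onset propensity but (by default)
not with the wake-after-sleep-onset propensity.

The generative model (all latent quantities on a 1-minute grid so that
noiseless discretization at 60-s or 30-s epochs is exact):

* lights-off clock time ~ Normal(22:30, lights_off_sd) per night;
* nightly SOL ~ log-normal with child-specific mean
  ``M_c = sol_base + group_sol_shift·1[autism] + u_f + sol_child_sd·z_c``
  (family intercept u_f ~ N(0, family_sd); z_c ~ N(0,1)) and
  night-to-night CV ``night_sd / sol_base`` — non-negative and
  right-skewed, reproducing the long-latency outlier tail;
* sleep-period length ~ Normal(mean_tst + family intercept, night_sd);
* wake bouts: Poisson(awakening_rate) count per night, exponential
  durations with child-modulated mean, placed uniformly inside the sleep
  period at least 10 min clear of onset and final awakening;
* behavior liability = r_sol·ẑ(SOL propensity) + r_waso·ẑ(WASO propensity)
  + independent noise, rescaled per questionnaire scale.

All distributional forms are stand-ins chosen for qualitative realism; no
real recordings inform them. All randomness flows from one root seed via
named per-(family, child, night, device) streams, so identical
(spec, seed) reproduces byte-identical output.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from datetime import date, timedelta
from typing import Optional

import numpy as np
import pandas as pd

from .dtypes import MISSING, SLEEP, STAGES, WAKE, EpochSeries
from .timeutils import night_datetime

_STAGE_CYCLE = ("N1", "N2", "N3", "N2", "REM")  # crude ultradian progression


@dataclass(frozen=True)
class DeviceModel:
    """Observation model for one recording device."""

    name: str
    epoch_s: int = 60
    miss_rate: float = 0.0            # P(flip sleep<->wake) per epoch
    extra_brief_wake_rate: float = 0.0  # mean spurious <=5-min wake bouts/night
    dropout_prob: float = 0.0         # P(night not recorded)
    n_channels: int = 1
    channel_disagreement: float = 0.0  # per-channel stage-flip probability
    staged: bool = False              # emit 5-stage labels (EEG dialects)

    def __post_init__(self) -> None:
        if self.epoch_s not in (30, 60):
            raise ValueError(f"device {self.name}: epoch_s must be 30 or 60")
        for f in ("miss_rate", "extra_brief_wake_rate", "dropout_prob",
                  "channel_disagreement"):
            v = getattr(self, f)
            if f == "extra_brief_wake_rate":
                if v < 0:
                    raise ValueError(f"device {self.name}: {f} must be >= 0")
            elif not 0.0 <= v <= 1.0:
                raise ValueError(f"device {self.name}: {f} must be in [0, 1]")
        if self.n_channels < 1:
            raise ValueError(f"device {self.name}: n_channels must be >= 1")


def default_devices() -> list[DeviceModel]:
    """Three-device roster mirroring the smartwatch / mat / EEG setup."""
    return [
        DeviceModel(name="watch", epoch_s=60, miss_rate=0.04,
                    extra_brief_wake_rate=3.0, dropout_prob=0.10),
        DeviceModel(name="mat", epoch_s=60, miss_rate=0.04,
                    extra_brief_wake_rate=0.3, dropout_prob=0.10),
        DeviceModel(name="eeg", epoch_s=30, miss_rate=0.02,
                    extra_brief_wake_rate=0.2, dropout_prob=0.15,
                    n_channels=4, channel_disagreement=0.08, staged=True),
    ]


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of the synthetic cohort.

    Defaults give a cohort of 100 families (one autistic child + one
    sibling each), ~2 weeks of nights per child, a 7.5-min latent mean SOL
    shift in the autistic group, and a behavior liability correlated 0.3
    with the child-level SOL propensity and 0 with the WASO propensity.
    """

    n_families: int = 100
    nights_min: int = 10
    nights_max: int = 16
    group_sol_shift: float = 7.5      # min, autism - sibling latent mean SOL
    family_sd: float = 8.0            # min, between-family intercept SD
    night_sd: float = 30.0            # min, night-to-night SD (TST; scales SOL CV)
    mean_tst: float = 480.0           # min
    awakening_rate: float = 3.0       # Poisson mean bouts/night
    awakening_duration: float = 8.0   # min, mean exponential bout length
    behavior_sol_corr: float = 0.3
    behavior_waso_corr: float = 0.0
    sol_waso_propensity_corr: float = 0.4  # children with long onsets also
    # tend to wake more: child-level correlation of the two propensities
    device_models: tuple[DeviceModel, ...] = field(
        default_factory=lambda: tuple(default_devices()))
    seed: int = 0
    # secondary knobs (single study condition; rarely changed)
    sol_base: float = 20.0            # min, sibling-group latent mean SOL
    sol_child_sd: float = 12.0        # min, child-level SOL propensity SD
    sol_night_sd: Optional[float] = None  # min, nightly SOL SD at the base
    # mean; None -> 0.4 * night_sd (SOL varies less night-to-night than TST)
    tst_family_sd: float = 40.0       # min, family TST intercept SD (shared
    # schedules dominate sleep-duration variance: family ICC ~ 0.5)
    lights_off_sd: float = 40.0       # min, nightly lights-off jitter
    waso_child_lognorm_sd: float = 0.35
    diary_bias: float = 5.0           # min, systematic parent-report shift
    diary_sd: float = 10.0            # min, parent-report noise
    diary_waso_factor: float = 0.6    # parents under-report WASO
    start_date: date = date(2023, 3, 1)
    post_fa_wake_min: int = 150       # recorded wake tail after FA

    def __post_init__(self) -> None:
        if self.n_families < 1:
            raise ValueError("n_families must be >= 1")
        if not 1 <= self.nights_min <= self.nights_max:
            raise ValueError("need 1 <= nights_min <= nights_max")
        for f in ("family_sd", "night_sd", "sol_child_sd", "lights_off_sd",
                  "awakening_rate", "awakening_duration", "diary_sd",
                  "tst_family_sd"):
            if getattr(self, f) < 0:
                raise ValueError(f"{f} must be >= 0")
        if self.sol_night_sd is not None and self.sol_night_sd < 0:
            raise ValueError("sol_night_sd must be >= 0")
        for f in ("behavior_sol_corr", "behavior_waso_corr"):
            if abs(getattr(self, f)) > 1:
                raise ValueError(f"|{f}| must be <= 1")
        if abs(self.sol_waso_propensity_corr) >= 1:
            raise ValueError("|sol_waso_propensity_corr| must be < 1")
        if abs(self.behavior_sol_corr) ** 2 + abs(self.behavior_waso_corr) ** 2 > 1:
            raise ValueError("behavior correlations imply negative residual variance")


@dataclass
class TrueNight:
    """Latent ground truth for one child-night (minutes on a 1-min grid)."""

    child_id: str
    night_date: date
    lights_off_noon_min: int   # lights-off / recording start, minutes from anchor noon
    sol_min: int               # latent sleep-onset latency
    sleep_period_min: int      # FA - SO
    wake_bouts: tuple[tuple[int, int], ...]  # (offset from SO, duration) min

    def __post_init__(self) -> None:
        end = self.sleep_period_min
        prev_end = 0
        for off, dur in self.wake_bouts:
            if off < prev_end or off + dur > end or dur < 1:
                raise ValueError("wake bouts must be disjoint and inside (SO, FA)")
            prev_end = off + dur
        if self.sol_min < 0:
            raise ValueError("SOL must be >= 0")

    @property
    def so_noon_min(self) -> int:
        return self.lights_off_noon_min + self.sol_min

    @property
    def fa_noon_min(self) -> int:
        return self.so_noon_min + self.sleep_period_min

    @property
    def waso_total_min(self) -> int:
        return sum(d for _, d in self.wake_bouts)

    @property
    def waso_over5_min(self) -> int:
        """WASO counting only bouts > 5 min (the brief-wake-exclusion view)."""
        return sum(d for _, d in self.wake_bouts if d > 5)

    @property
    def tst_min(self) -> int:
        return self.sleep_period_min - self.waso_total_min

    def binary_minutes(self, post_fa_wake_min: int) -> np.ndarray:
        """Latent per-minute SLEEP/WAKE trace from recording start to end."""
        n = self.sol_min + self.sleep_period_min + post_fa_wake_min
        lab = np.full(n, SLEEP, dtype=object)
        lab[: self.sol_min] = WAKE
        for off, dur in self.wake_bouts:
            lab[self.sol_min + off: self.sol_min + off + dur] = WAKE
        lab[self.sol_min + self.sleep_period_min:] = WAKE
        return lab


def _rng(seed: int, *key: int) -> np.random.Generator:
    """Named child stream: one root seed, stable per-(family,child,night,device)."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=tuple(key)))


# stream namespaces (first element of the spawn key)
_NS_FAMILY, _NS_NIGHT, _NS_DEVICE, _NS_DIARY, _NS_BEHAVIOR, _NS_CSHQ = range(6)


def simulate_night(spec: CohortSpec, family: int, child: int, night_idx: int,
                   child_mean_sol: float, family_tst_shift: float,
                   waso_factor: float) -> TrueNight:
    """Draw one latent night on the 1-minute grid."""
    rng = _rng(spec.seed, _NS_NIGHT, family, child, night_idx)
    child_id = _child_id(family, child)
    night = spec.start_date + timedelta(days=night_idx)

    lights_off = int(round(rng.normal(630.0, spec.lights_off_sd)))  # 22:30 anchor

    mean_sol = max(child_mean_sol, 1.0)
    sol_night_sd = (0.4 * spec.night_sd if spec.sol_night_sd is None
                    else spec.sol_night_sd)
    cv = sol_night_sd / spec.sol_base
    sigma2 = np.log1p(cv ** 2)
    mu = np.log(mean_sol) - sigma2 / 2.0
    sol = int(round(rng.lognormal(mu, np.sqrt(sigma2))))

    sleep_period = int(round(np.clip(
        rng.normal(spec.mean_tst + family_tst_shift, spec.night_sd), 240, 840)))

    k = rng.poisson(spec.awakening_rate)
    k = min(k, max((sleep_period - 20) // 12, 0))
    bouts: list[tuple[int, int]] = []
    if k > 0:
        durs = np.maximum(1, np.round(
            rng.exponential(spec.awakening_duration * waso_factor, size=k))).astype(int)
        # insertion offsets in sleep time, >=10 min clear of SO and FA,
        # >=1 min of sleep between consecutive bouts
        lo, hi = 10, sleep_period - 10 - int(durs.sum()) - k
        if hi > lo:
            offs = np.sort(rng.integers(lo, hi, size=k))
            shift = 0
            for j in range(k):
                start = int(offs[j]) + shift + j  # j spacer minutes
                bouts.append((start, int(durs[j])))
                shift += int(durs[j])
    return TrueNight(child_id=child_id, night_date=night,
                     lights_off_noon_min=lights_off, sol_min=sol,
                     sleep_period_min=sleep_period, wake_bouts=tuple(bouts))


def _child_id(family: int, child: int) -> str:
    return f"F{family:03d}C{child}"


def observe_device(true_night: TrueNight, model: DeviceModel,
                   rng: np.random.Generator,
                   post_fa_wake_min: int = 150) -> EpochSeries:
    """Corrupt a latent night through one device's observation model.

    Discretizes the 1-minute latent trace at the device's epoch size, flips
    epochs sleep<->wake with ``miss_rate``, injects spurious <=5-min wake
    bouts inside the sleep period, and — for staged devices — expands sleep
    into a crude stage progression replicated over ``n_channels`` with
    independent per-channel disagreement plus a confidence per epoch.
    """
    minute_lab = true_night.binary_minutes(post_fa_wake_min)
    per_min = 60 // model.epoch_s  # epochs per minute (1 or 2)
    lab = np.repeat(minute_lab, per_min)
    n = len(lab)

    if model.miss_rate > 0:
        flip = rng.random(n) < model.miss_rate
        lab = lab.copy()
        lab[flip] = np.where(lab[flip] == SLEEP, WAKE, SLEEP)

    n_extra = rng.poisson(model.extra_brief_wake_rate)
    so_e = true_night.sol_min * per_min
    fa_e = (true_night.sol_min + true_night.sleep_period_min) * per_min
    if n_extra > 0 and fa_e - so_e > 12 * per_min:
        lab = lab.copy()
        for _ in range(n_extra):
            dur_min = int(rng.integers(1, 6))  # 1..5 min, stays "brief"
            start = int(rng.integers(so_e + 6 * per_min,
                                     fa_e - 6 * per_min - dur_min * per_min))
            lab[start: start + dur_min * per_min] = WAKE

    start_dt = night_datetime(true_night.night_date,
                              true_night.lights_off_noon_min)
    base = EpochSeries(child_id=true_night.child_id,
                       night_date=true_night.night_date, device=model.name,
                       recording_start=start_dt, epoch_s=model.epoch_s,
                       labels=lab)
    if not model.staged:
        return base
    return _stage_and_split(base, model, rng)


def _stage_and_split(base: EpochSeries, model: DeviceModel,
                     rng: np.random.Generator) -> EpochSeries:
    """Expand binary labels into per-channel stage labels + confidences."""
    n = base.n_epochs
    true_stage = np.empty(n, dtype=object)
    cycle_pos = 0
    epochs_per_stage = max(1, (20 * 60) // base.epoch_s // len(_STAGE_CYCLE))
    run = 0
    for i in range(n):
        if base.labels[i] == WAKE:
            true_stage[i] = "W"
            run = 0
        else:
            true_stage[i] = _STAGE_CYCLE[cycle_pos]
            run += 1
            if run >= epochs_per_stage:
                run = 0
                cycle_pos = (cycle_pos + 1) % len(_STAGE_CYCLE)
    ch_labels = np.tile(true_stage, (model.n_channels, 1))
    conf = rng.uniform(0.6, 1.0, size=ch_labels.shape)
    if model.channel_disagreement > 0:
        flip = rng.random(ch_labels.shape) < model.channel_disagreement
        alt = rng.integers(0, len(STAGES), size=ch_labels.shape)
        for c in range(model.n_channels):
            for i in np.nonzero(flip[c])[0]:
                choices = [s for s in STAGES if s != ch_labels[c, i]]
                ch_labels[c, i] = choices[alt[c, i] % len(choices)]
                conf[c, i] = rng.uniform(0.2, 0.6)
    return dataclasses.replace(base, labels=ch_labels, confidence=conf)


def simulate_diary(true_night: TrueNight, rng: np.random.Generator,
                   reporter_bias: float = 0.0, reporter_sd: float = 0.0,
                   waso_factor: float = 1.0) -> dict:
    """Parent diary row: biased, noisy SO/FA rounded to 5 min; scaled WASO."""
    if reporter_sd < 0:
        raise ValueError("reporter_sd must be >= 0")
    so = true_night.so_noon_min + reporter_bias + rng.normal(0, reporter_sd)
    fa = true_night.fa_noon_min + reporter_bias + rng.normal(0, reporter_sd)
    so = 5 * round(so / 5)
    fa = 5 * round(fa / 5)
    waso = max(0.0, true_night.waso_total_min * waso_factor
               + (rng.normal(0, reporter_sd) if reporter_sd > 0 else 0.0))
    return {
        "child_id": true_night.child_id,
        "night_date": true_night.night_date.isoformat(),
        "so_noon_min": float(so),
        "fa_noon_min": float(fa),
        "waso_min": float(round(waso)),
    }


_BEHAVIOR_SCALES = {
    # scale -> (mean, sd, direction): +1 higher score = more difficulties
    "srs_total": (60.0, 25.0, +1),
    "rbsr_total": (15.0, 15.0, +1),
    "cbcl_adhd": (55.0, 8.0, +1),
    "cbcl_anxiety": (55.0, 8.0, +1),
    "cbcl_depression": (55.0, 8.0, +1),
    "cshq_total": (45.0, 8.0, +1),
    "vineland_composite": (90.0, 15.0, -1),
    "sensory_sensitivity": (10.0, 4.0, +1),
}


def simulate_truth(spec: CohortSpec):
    """Latent cohort only (no device observation, diary or hypnograms).

    Returns ``(roster, true_nights, behavior)`` — the cheap path for
    Monte-Carlo studies of the statistical stages, identical in law to the
    latent layer of :func:`simulate_cohort` under the same spec and seed.
    """
    roster, true_nights, _rec, _diary, behavior, _truths = simulate_cohort(
        spec, with_devices=False, with_diary=False)
    return roster, true_nights, behavior


def simulate_cohort(spec: CohortSpec, with_devices: bool = True,
                    with_diary: bool = True):
    """Generate the full synthetic cohort.

    Returns ``(roster, true_nights, recordings, diary, behavior, truths)``
    where

    * ``roster`` — DataFrame: child_id, family_id, diagnosis, age, sex,
      plus the latent child-level SOL/WASO propensities (ground truth);
    * ``true_nights`` — DataFrame of latent per-night values (SO/FA/WASO/
      TST/SOL on the noon axis);
    * ``recordings`` — dict (child_id, night_iso, device) -> EpochSeries;
    * ``diary`` — DataFrame of parent-reported SO/FA/WASO per night;
    * ``behavior`` — DataFrame of questionnaire scores per child;
    * ``truths`` — dict (child_id, night_iso) -> TrueNight (bout lists kept
      for exact ground-truth checks).
    """
    roster_rows = []
    night_rows = []
    bout_lists: dict[tuple[str, str], TrueNight] = {}
    recordings: dict[tuple[str, str, str], EpochSeries] = {}
    diary_rows = []
    cshq_rows = []

    sol_props = []   # child-level latent mean SOL (the SOL propensity)
    waso_props = []  # child-level latent WASO modulation factor
    child_ids = []

    for fam in range(spec.n_families):
        frng = _rng(spec.seed, _NS_FAMILY, fam)
        u_sol = frng.normal(0, spec.family_sd)
        u_tst = frng.normal(0, spec.tst_family_sd)
        n_nights = int(frng.integers(spec.nights_min, spec.nights_max + 1))
        for child, dx in enumerate(("autism", "sibling")):
            cid = _child_id(fam, child)
            z_sol = frng.normal()
            rho = spec.sol_waso_propensity_corr
            z_waso = rho * z_sol + np.sqrt(1 - rho ** 2) * frng.normal()
            mean_sol = (spec.sol_base
                        + (spec.group_sol_shift if dx == "autism" else 0.0)
                        + u_sol + spec.sol_child_sd * z_sol)
            waso_factor = float(np.exp(spec.waso_child_lognorm_sd * z_waso
                                       - spec.waso_child_lognorm_sd ** 2 / 2))
            age = float(np.round(frng.uniform(10, 17), 1))
            sex = "M" if frng.random() < (0.84 if dx == "autism" else 0.53) else "F"
            roster_rows.append({
                "child_id": cid, "family_id": f"F{fam:03d}", "diagnosis": dx,
                "age": age, "sex": sex,
                "latent_mean_sol": mean_sol, "latent_waso_factor": waso_factor,
            })
            child_ids.append(cid)
            sol_props.append(mean_sol)
            waso_props.append(np.log(waso_factor))

            child_nights: list[TrueNight] = []
            for nt in range(n_nights):
                tn = simulate_night(spec, fam, child, nt, mean_sol, u_tst,
                                    waso_factor)
                child_nights.append(tn)
                bout_lists[(cid, tn.night_date.isoformat())] = tn
                night_rows.append({
                    "child_id": cid, "family_id": f"F{fam:03d}", "diagnosis": dx,
                    "night_date": tn.night_date.isoformat(),
                    "lights_off_noon_min": tn.lights_off_noon_min,
                    "so_noon_min": tn.so_noon_min,
                    "fa_noon_min": tn.fa_noon_min,
                    "sol_min": tn.sol_min,
                    "waso_total_min": tn.waso_total_min,
                    "waso_over5_min": tn.waso_over5_min,
                    "tst_min": tn.tst_min,
                    "sleep_period_min": tn.sleep_period_min,
                })
                if with_devices:
                    for di, model in enumerate(spec.device_models):
                        drng = _rng(spec.seed, _NS_DEVICE, fam, child, nt, di)
                        if drng.random() < model.dropout_prob:
                            continue
                        recordings[(cid, tn.night_date.isoformat(), model.name)] = \
                            observe_device(tn, model, drng, spec.post_fa_wake_min)
                if with_diary:
                    diary_rows.append(simulate_diary(
                        tn, _rng(spec.seed, _NS_DIARY, fam, child, nt),
                        reporter_bias=spec.diary_bias, reporter_sd=spec.diary_sd,
                        waso_factor=spec.diary_waso_factor))
            cshq_rows.append(_simulate_cshq_report(
                spec, cid, child_nights,
                _rng(spec.seed, _NS_CSHQ, fam, child)))

    roster = pd.DataFrame(roster_rows)
    true_nights = pd.DataFrame(night_rows)
    diary = pd.DataFrame(diary_rows)
    behavior = _simulate_behavior(spec, child_ids, np.asarray(sol_props),
                                  np.asarray(waso_props))
    behavior = behavior.merge(pd.DataFrame(cshq_rows), on="child_id")
    roster = roster.merge(behavior[["child_id", "liability"]], on="child_id")
    return roster, true_nights, recordings, diary, behavior, bout_lists


def _simulate_cshq_report(spec: CohortSpec, cid: str,
                          nights: list[TrueNight],
                          rng: np.random.Generator) -> dict:
    """Questionnaire 'typical night' items: weekday/weekend SO and FA clock
    times (biased, noisy, rounded to 15 min) plus one WASO value."""
    so_mean = float(np.mean([tn.so_noon_min for tn in nights]))
    fa_mean = float(np.mean([tn.fa_noon_min for tn in nights]))
    waso_mean = float(np.mean([tn.waso_total_min for tn in nights]))
    b, s = spec.diary_bias, spec.diary_sd

    def _rep(center: float, shift: float) -> float:
        return 15.0 * round((center + shift + b + rng.normal(0, s)) / 15.0)

    return {
        "child_id": cid,
        "cshq_weekday_so_noon_min": _rep(so_mean, -10.0),
        "cshq_weekend_so_noon_min": _rep(so_mean, +25.0),
        "cshq_weekday_fa_noon_min": _rep(fa_mean, -15.0),
        "cshq_weekend_fa_noon_min": _rep(fa_mean, +30.0),
        "cshq_waso_min": max(0.0, round(
            waso_mean * spec.diary_waso_factor + rng.normal(0, s))),
    }


def _simulate_behavior(spec: CohortSpec, child_ids, sol_props, waso_props
                       ) -> pd.DataFrame:
    """Questionnaire scores with controlled latent correlations.

    Liability = α·ẑ(SOL propensity) + β·ẑ(WASO propensity) + noise, where ẑ
    standardizes across the realized cohort and (α, β) solve the normal
    equations against the realized propensity correlation, so the sample
    correlations of liability with the SOL and WASO propensities converge
    to ``behavior_sol_corr`` and ``behavior_waso_corr`` even though the two
    propensities are themselves correlated.
    """
    rng = _rng(spec.seed, _NS_BEHAVIOR)
    z_sol = _standardize(sol_props)
    z_waso = _standardize(waso_props)
    r1, r2 = spec.behavior_sol_corr, spec.behavior_waso_corr
    if len(z_sol) > 2 and z_sol.std() > 0 and z_waso.std() > 0:
        rho = float(np.corrcoef(z_sol, z_waso)[0, 1])
    else:
        rho = 0.0
    denom = max(1.0 - rho ** 2, 1e-9)
    alpha = (r1 - r2 * rho) / denom
    beta = (r2 - r1 * rho) / denom
    explained = alpha ** 2 + beta ** 2 + 2 * alpha * beta * rho
    resid = np.sqrt(max(1.0 - explained, 0.0))
    liability = (alpha * z_sol + beta * z_waso
                 + resid * rng.normal(size=len(z_sol)))
    rows = {"child_id": list(child_ids), "liability": liability}
    for scale, (mean, sd, sign) in _BEHAVIOR_SCALES.items():
        loading = 0.95  # scales are strong, noisy readouts of one liability
        noise = rng.normal(size=len(z_sol))
        score = mean + sign * sd * (loading * liability
                                    + np.sqrt(1 - loading ** 2) * noise)
        rows[scale] = np.round(score, 1)
    return pd.DataFrame(rows)


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    if sd == 0:
        return np.zeros_like(x, dtype=float)
    return (x - x.mean()) / sd
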