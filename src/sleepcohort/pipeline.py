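"""End-to-end orchestration: simulate -> extract -> filter -> agree ->
model -> dissociate -> report.

Each stage writes tidy CSV artifacts under the configured output
directory; a manifest records the seed and a hash of the full config so a
rerun with identical settings reproduces identical artifacts byte for
byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from datetime import date
from pathlib import Path

import numpy as np
import pandas as pd

from . import agreement as agr
from . import cohort as coh
from . import dissociation as dis
from . import groupstats as gs
from . import hypnogram as hyp
from . import io as scio
from .config import PipelineConfig, config_hash
from .dtypes import DIALECTS, EpochSeries, NightMetrics
from .simulate import simulate_cohort
from .timeutils import minutes_since_noon, night_datetime

log = logging.getLogger("sleepcohort")

# device -> extraction rule dialect; the EEG stream is additionally scored
# under the external-stager dialect as a second, independent estimate.
DEVICE_DIALECTS = {"watch": "embrace", "mat": "eeg_algo", "eeg": "eeg_algo"}
EEG_SECOND_DIALECT = ("eeg", "eeg_ext", "eeg_external")


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def stage_simulate(cfg: PipelineConfig, out: Path):
    spec = cfg.cohort_spec()
    roster, truth, recordings, diary, behavior, truths = simulate_cohort(spec)
    roster.to_csv(out / "roster.csv", index=False)
    truth.to_csv(out / "true_nights.csv", index=False)
    diary.to_csv(out / "diary.csv", index=False)
    behavior.to_csv(out / "behavior.csv", index=False)
    if cfg.write_hypnograms:
        hdir = out / "hypnograms"
        hdir.mkdir(exist_ok=True)
        for (cid, night, device), series in recordings.items():
            stem = f"{cid}_{night}_{device}"
            if series.is_multichannel:
                scio.write_hypnogram_csv(series, hdir / f"{stem}.csv")
            else:
                scio.write_hypnogram_txt(series, hdir / f"{stem}.txt")
    log.info("simulated %d children, %d nights, %d device recordings",
             len(roster), len(truth), len(recordings))
    return roster, truth, recordings, diary, behavior, truths


def extract_night(series: EpochSeries, dialect_name: str,
                  source: str | None = None,
                  channel_mode: str = "majority") -> NightMetrics:
    """Reduce channels, binarize as needed, then extract under a dialect.

    ``channel_mode='majority'`` takes the cross-channel majority vote (the
    external-stager route); ``channel_mode='first'`` scores from the first
    channel only (emulating a device's built-in single-stream algorithm),
    so the two routes give genuinely independent estimates when channels
    disagree. For multi-channel input the quality score is 100x the mean
    per-epoch confidence of the recording.
    """
    import dataclasses as _dc

    quality = None
    if series.is_multichannel:
        if series.confidence is not None:
            quality = float(100.0 * series.confidence.mean())
        if channel_mode == "first":
            series = _dc.replace(
                series, labels=series.labels[0],
                confidence=None if series.confidence is None
                else series.confidence[0])
        else:
            series = hyp.majority_vote(series)
    if any(l in hyp.STAGES for l in series.labels):
        series = hyp.binarize_stages(series)
    m = hyp.extract_metrics(series, DIALECTS[dialect_name],
                            quality_score=quality)
    if source is not None:
        m.device = source
    return m


def stage_extract(cfg: PipelineConfig, recordings: dict, out: Path
                  ) -> list[NightMetrics]:
    metrics: list[NightMetrics] = []
    n_unusable = 0
    for (cid, night, device), series in sorted(recordings.items()):
        # the EEG stream is scored twice: by its "own" single-stream
        # algorithm (first channel) and by the external majority-vote stager
        jobs = [(device, DEVICE_DIALECTS.get(device, "eeg_algo"),
                 "first" if device == EEG_SECOND_DIALECT[0] else "majority")]
        if device == EEG_SECOND_DIALECT[0]:
            jobs.append((EEG_SECOND_DIALECT[1], EEG_SECOND_DIALECT[2],
                         "majority"))
        for source, dialect, mode in jobs:
            try:
                metrics.append(extract_night(series, dialect, source=source,
                                             channel_mode=mode))
            except (hyp.NoSleepOnsetError, hyp.NoFinalAwakeningError) as exc:
                n_unusable += 1
                log.debug("unusable night %s %s %s: %s", cid, night, source, exc)
    scio.write_metrics_csv(metrics, out / "night_metrics.csv")
    log.info("extracted %d device-nights (%d unusable)", len(metrics), n_unusable)
    return metrics


def diary_to_metrics(diary: pd.DataFrame) -> list[NightMetrics]:
    """Diary rows (noon-anchored minutes) -> NightMetrics via the TST rule."""
    out = []
    for _, r in diary.iterrows():
        night = date.fromisoformat(r["night_date"])
        so = night_datetime(night, float(r["so_noon_min"]))
        fa = night_datetime(night, float(r["fa_noon_min"]))
        try:
            m = hyp.diary_metrics(str(r["child_id"]), night, so.time(),
                                  fa.time(), float(r["waso_min"]))
        except ValueError as exc:
            log.debug("diary row dropped (%s %s): %s",
                      r["child_id"], r["night_date"], exc)
            continue
        out.append(m)
    return out


def cshq_table(behavior: pd.DataFrame) -> pd.DataFrame:
    """Per-child questionnaire sleep measures on the noon-minute axis."""
    rows = []
    for _, r in behavior.iterrows():
        m = hyp.cshq_metrics(
            str(r["child_id"]),
            night_datetime(date(2000, 1, 2), r["cshq_weekday_so_noon_min"]).time(),
            night_datetime(date(2000, 1, 2), r["cshq_weekday_fa_noon_min"]).time(),
            night_datetime(date(2000, 1, 2), r["cshq_weekend_so_noon_min"]).time(),
            night_datetime(date(2000, 1, 2), r["cshq_weekend_fa_noon_min"]).time(),
            float(r["cshq_waso_min"]))
        rows.append({
            "child_id": str(r["child_id"]),
            "so_noon_min": minutes_since_noon(m.so),
            "fa_noon_min": minutes_since_noon(m.fa),
            "waso_min": m.waso_min,
            "tst_min": m.tst_min,
        })
    return pd.DataFrame(rows)


def stage_build_cohort(cfg: PipelineConfig, metrics: list[NightMetrics],
                       diary: pd.DataFrame, roster: pd.DataFrame, out: Path):
    th = cfg.validity()
    all_metrics = metrics + diary_to_metrics(diary)
    table = coh.metrics_to_frame(all_metrics, roster=roster, th=th)
    table = coh.keep_main_sleep_period(table)
    required = cfg.required_sources
    if required is None:
        required = [s for s in ("watch", "mat", "eeg", "diary")
                    if s in set(table["source"])]
    selected, group_counts = coh.select_analysis_cohort(
        table, min_valid_nights=cfg.min_valid_nights,
        required_sources=required)
    overlap = coh.device_night_overlap(
        table, devices=[s for s in required if s != "diary"])
    table.to_csv(out / "night_table.csv", index=False)
    selected.to_csv(out / "analysis_cohort.csv", index=False)
    group_counts.to_csv(out / "cohort_counts.csv", index=False)
    (out / "device_overlap.json").write_text(json.dumps(overlap, indent=2))
    log.info("cohort: %d/%d rows retained; children per group: %s",
             len(selected), len(table),
             dict(zip(group_counts.get("diagnosis", []),
                      group_counts.get("n_children", []))))
    return table, selected, overlap


def stage_agreement(cfg: PipelineConfig, selected: pd.DataFrame,
                    behavior: pd.DataFrame, out: Path):
    sources = [s for s in ("watch", "mat", "eeg", "diary")
               if s in set(selected["source"])]
    per_night = agr.agreement_matrix(selected, level="per_night",
                                     sources=sources,
                                     n_iter=cfg.agreement_n_iter,
                                     seed=cfg.seed)
    cshq = cshq_table(behavior)
    per_child = agr.agreement_matrix(selected, level="per_child",
                                     sources=sources, cshq=cshq,
                                     n_iter=cfg.agreement_n_iter,
                                     seed=cfg.seed + 1)
    per_night.to_csv(out / "agreement_per_night.csv", index=False)
    per_child.to_csv(out / "agreement_per_child.csv", index=False)
    return per_night, per_child


def stage_epoch_confusion(recordings: dict, out: Path,
                          ref_device: str = "eeg", other: str = "watch"
                          ) -> pd.DataFrame:
    """Per-night epoch-level sleep/wake concordance between two devices.

    The EEG stream (majority-voted, binarized) is the reference; reports
    the other device's sensitivity (sleep detection) and specificity (wake
    detection) per shared night.
    """
    rows = []
    by_night: dict = {}
    for (cid, night, device), series in recordings.items():
        by_night.setdefault((cid, night), {})[device] = series
    for (cid, night), devs in sorted(by_night.items()):
        if ref_device not in devs or other not in devs:
            continue
        ref = devs[ref_device]
        if ref.is_multichannel:
            ref = hyp.binarize_stages(hyp.majority_vote(ref))
        try:
            sens, spec = agr.epoch_confusion(ref, devs[other])
        except ValueError:
            continue
        rows.append({"child_id": cid, "night_date": night,
                     "sensitivity": sens, "specificity": spec})
    df = pd.DataFrame(rows)
    df.to_csv(out / "epoch_confusion.csv", index=False)
    if len(df):
        log.info("epoch-level %s vs %s: sensitivity %.2f, specificity %.2f "
                 "(%d nights)", other, ref_device,
                 df["sensitivity"].mean(),
                 df["specificity"].dropna().mean(), len(df))
    return df


def stage_models(cfg: PipelineConfig, selected: pd.DataFrame,
                 roster: pd.DataFrame, behavior: pd.DataFrame, out: Path
                 ) -> pd.DataFrame:
    rows = []
    for outcome in cfg.sleep_outcomes:
        for source in sorted(selected["source"].unique()):
            sub = selected[selected["source"] == source]
            try:
                res = gs.fit_family_lmm(sub, outcome)
            except (gs.ConvergenceError, ValueError) as exc:
                log.warning("model %s/%s failed: %s", outcome, source, exc)
                continue
            rows.append(_model_row(res, f"{outcome}[{source}]"))
    eeg = selected[(selected["source"] == "eeg")
                   & selected["sol_min"].notna()]
    if len(eeg):
        try:
            rows.append(_model_row(gs.fit_family_lmm(eeg, "sol_min"),
                                   "sol_min[eeg]"))
        except (gs.ConvergenceError, ValueError) as exc:
            log.warning("SOL model failed: %s", exc)
    child_tab = roster.merge(behavior, on="child_id")
    for scale in cfg.behavior_scales:
        try:
            rows.append(_model_row(gs.fit_family_lmm(child_tab, scale), scale))
        except (gs.ConvergenceError, ValueError) as exc:
            log.warning("model %s failed: %s", scale, exc)
    df = pd.DataFrame(rows)
    df.to_csv(out / "mixed_models.csv", index=False)
    return df


def _model_row(res, label: str) -> dict:
    return {
        "outcome": label,
        "beta_diagnosis": res.params.get("dx", np.nan),
        "se_diagnosis": res.bse.get("dx", np.nan),
        "p_diagnosis": res.pvalues.get("dx", np.nan),
        "beta_age": res.params.get("age", np.nan),
        "beta_sex": res.params.get("male", np.nan),
        "sigma2_between": res.sigma2_between,
        "sigma2_within": res.sigma2_within,
        "icc": res.icc,
        "f2_diagnosis": res.f2_diagnosis,
        "n_obs": res.n_obs,
        "n_families": res.n_groups,
    }


def per_child_eeg_sleep(selected: pd.DataFrame) -> pd.DataFrame:
    """Per-child mean SOL and WASO from the two EEG scoring routes."""
    out = None
    for source, tag in (("eeg", "eeg_algo"), ("eeg_ext", "eeg_external")):
        sub = selected[selected["source"] == source]
        g = sub.groupby("child_id").agg(
            **{f"sol_{tag}": ("sol_min", "mean"),
               f"waso_{tag}": ("waso_min", "mean")}).reset_index()
        out = g if out is None else out.merge(g, on="child_id", how="outer")
    return out if out is not None else pd.DataFrame(columns=["child_id"])


def stage_dissociation(cfg: PipelineConfig, selected: pd.DataFrame,
                       behavior: pd.DataFrame, out: Path) -> dict:
    per_child = per_child_eeg_sleep(selected)
    report = dis.run_dissociation(per_child, behavior,
                                  scales=cfg.behavior_scales)
    report["mean_matrix"].to_csv(out / "dissociation_mean.csv", index=False)
    report["steiger"].to_csv(out / "dissociation_steiger.csv", index=False)
    for a, m in report["per_algorithm"].items():
        m.to_csv(out / f"dissociation_{a}.csv", index=False)
    return report


def stage_report(cfg: PipelineConfig, out: Path, per_night, per_child,
                 models, dream_report) -> None:
    if not cfg.make_figures:
        return
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    for name, mat in (("agreement_per_night", per_night),
                      ("agreement_per_child", per_child)):
        measures = sorted(mat["measure"].unique())
        fig, axes = plt.subplots(1, len(measures),
                                 figsize=(4 * len(measures), 3.5))
        axes = np.atleast_1d(axes)
        for ax, measure in zip(axes, measures):
            sub = mat[mat["measure"] == measure]
            piv = sub.pivot(index="source_a", columns="source_b", values="ccc")
            im = ax.imshow(piv.values, vmin=-1, vmax=1, cmap="RdBu_r")
            ax.set_xticks(range(len(piv.columns)), piv.columns, rotation=45)
            ax.set_yticks(range(len(piv.index)), piv.index)
            ax.set_title(measure)
            for i in range(piv.shape[0]):
                for j in range(piv.shape[1]):
                    v = piv.values[i, j]
                    if np.isfinite(v):
                        ax.text(j, i, f"{v:.2f}", ha="center", va="center",
                                fontsize=7)
        fig.colorbar(im, ax=axes.tolist(), shrink=0.7, label="CCC")
        fig.savefig(out / f"{name}.png", dpi=120)
        plt.close(fig)

    mm = dream_report["mean_matrix"]
    piv = mm.pivot(index="sleep_measure", columns="scale", values="r")
    fig, ax = plt.subplots(figsize=(1.1 * piv.shape[1] + 2, 3))
    im = ax.imshow(piv.values, vmin=-0.5, vmax=0.5, cmap="RdBu_r")
    ax.set_xticks(range(piv.shape[1]), piv.columns, rotation=45, ha="right")
    ax.set_yticks(range(piv.shape[0]), piv.index)
    sig = mm.pivot(index="sleep_measure", columns="scale", values="significant")
    for i in range(piv.shape[0]):
        for j in range(piv.shape[1]):
            star = "*" if bool(sig.values[i, j]) else ""
            ax.text(j, i, f"{piv.values[i, j]:.2f}{star}",
                    ha="center", va="center", fontsize=7)
    fig.colorbar(im, ax=ax, label="Pearson r")
    ax.set_title("Behavior correlations of averaged EEG SOL/WASO "
                 "(* p<0.05, uncorrected)")
    fig.tight_layout()
    fig.savefig(out / "dissociation.png", dpi=120)
    plt.close(fig)


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run every stage in order; returns the in-memory artifacts."""
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), 20),
                        format="%(levelname)s %(name)s: %(message)s")
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    roster, truth, recordings, diary, behavior, truths = stage_simulate(cfg, out)
    metrics = stage_extract(cfg, recordings, out)
    table, selected, overlap = stage_build_cohort(cfg, metrics, diary,
                                                  roster, out)
    per_night, per_child = stage_agreement(cfg, selected, behavior, out)
    confusion = stage_epoch_confusion(recordings, out)
    models = stage_models(cfg, selected, roster, behavior, out)
    report = stage_dissociation(cfg, selected, behavior, out)
    stage_report(cfg, out, per_night, per_child, models, report)

    manifest = {
        "seed": cfg.seed,
        "config_hash": config_hash(cfg),
        "config": dataclasses.asdict(cfg),
        "n_children": int(roster.shape[0]),
        "n_true_nights": int(truth.shape[0]),
        "n_device_nights": len(recordings),
        "n_cohort_rows": int(selected.shape[0]),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  default=str))
    return {"roster": roster, "truth": truth, "recordings": recordings,
            "diary": diary, "behavior": behavior, "truths": truths,
            "metrics": metrics, "night_table": table, "cohort": selected,
            "overlap": overlap, "agreement_per_night": per_night,
            "agreement_per_child": per_child, "epoch_confusion": confusion,
            "models": models, "dissociation": report}
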