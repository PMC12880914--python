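"""Readers and writers for the pipeline's plain-text dialects.

Two hypnogram file dialects are supported:

* **stage-per-line txt** (external-stager style): `#`-prefixed header lines
  carry the metadata (child, night, device, start, epoch_s), then one label
  per line;
* **long CSV**: columns timestamp, channel, stage, confidence — the
  multi-channel EEG dialect.

Nightly metrics, rosters, diaries and behavior tables are tidy CSVs read
and written through pandas.
"""

from __future__ import annotations

from datetime import date, datetime
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .dtypes import EpochSeries, NightMetrics

_TS_FMT = "%Y-%m-%dT%H:%M:%S"


def write_hypnogram_txt(series: EpochSeries, path: Path | str) -> None:
    if series.is_multichannel:
        raise ValueError("txt dialect is single-channel; use the long CSV")
    lines = [
        f"# child_id={series.child_id}",
        f"# night_date={series.night_date.isoformat()}",
        f"# device={series.device}",
        f"# recording_start={series.recording_start.strftime(_TS_FMT)}",
        f"# epoch_s={series.epoch_s}",
    ]
    lines.extend(str(l) for l in series.labels)
    Path(path).write_text("\n".join(lines) + "\n")


def read_hypnogram_txt(path: Path | str) -> EpochSeries:
    meta: dict[str, str] = {}
    labels: list[str] = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            key, _, val = line.lstrip("# ").partition("=")
            meta[key.strip()] = val.strip()
        else:
            labels.append(line)
    try:
        return EpochSeries(
            child_id=meta["child_id"],
            night_date=date.fromisoformat(meta["night_date"]),
            device=meta["device"],
            recording_start=datetime.strptime(meta["recording_start"], _TS_FMT),
            epoch_s=int(meta["epoch_s"]),
            labels=np.array(labels, dtype=object),
        )
    except KeyError as exc:
        raise ValueError(f"{path}: missing header field {exc}") from exc


def write_hypnogram_csv(series: EpochSeries, path: Path | str) -> None:
    """Long CSV (timestamp, channel, stage, confidence), multi-channel OK."""
    n_ch = series.n_channels
    labels = series.labels if series.is_multichannel else series.labels[None, :]
    conf = series.confidence
    if conf is None:
        conf = np.ones_like(labels, dtype=float)
    elif not series.is_multichannel:
        conf = conf[None, :]
    rows = []
    for i in range(series.n_epochs):
        ts = series.epoch_time(i).strftime(_TS_FMT)
        for c in range(n_ch):
            rows.append((ts, c, labels[c, i], round(float(conf[c, i]), 4)))
    df = pd.DataFrame(rows, columns=["timestamp", "channel", "stage",
                                     "confidence"])
    with open(path, "w") as fh:
        fh.write(f"# child_id={series.child_id}\n")
        fh.write(f"# night_date={series.night_date.isoformat()}\n")
        fh.write(f"# device={series.device}\n")
        fh.write(f"# epoch_s={series.epoch_s}\n")
        df.to_csv(fh, index=False)


def read_hypnogram_csv(path: Path | str) -> EpochSeries:
    meta: dict[str, str] = {}
    with open(path) as fh:
        pos = fh.tell()
        while True:
            line = fh.readline()
            if line.startswith("#"):
                key, _, val = line.lstrip("# ").partition("=")
                meta[key.strip()] = val.strip()
                pos = fh.tell()
            else:
                fh.seek(pos)
                break
        df = pd.read_csv(fh)
    channels = sorted(df["channel"].unique())
    times = sorted(df["timestamp"].unique())
    wide_l = df.pivot(index="channel", columns="timestamp", values="stage")
    wide_c = df.pivot(index="channel", columns="timestamp", values="confidence")
    labels = wide_l.loc[channels, times].to_numpy(dtype=object)
    conf = wide_c.loc[channels, times].to_numpy(dtype=float)
    if labels.shape[0] == 1:
        labels, conf = labels[0], conf[0]
    return EpochSeries(
        child_id=meta["child_id"],
        night_date=date.fromisoformat(meta["night_date"]),
        device=meta["device"],
        recording_start=datetime.strptime(times[0], _TS_FMT),
        epoch_s=int(meta["epoch_s"]),
        labels=labels,
        confidence=conf,
    )


def write_metrics_csv(metrics: Iterable[NightMetrics], path: Path | str) -> None:
    rows = [{
        "child_id": m.child_id,
        "night_date": m.night_date.isoformat(),
        "device": m.device,
        "dialect": m.dialect,
        "so": m.so.strftime(_TS_FMT),
        "fa": m.fa.strftime(_TS_FMT),
        "waso_min": m.waso_min,
        "tst_min": m.tst_min,
        "sol_min": m.sol_min,
        "sol_outlier": m.sol_outlier,
        "quality_score": m.quality_score,
        "missing_frac": round(m.missing_frac, 4),
        "usable": m.usable,
    } for m in metrics]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_metrics_csv(path: Path | str) -> list[NightMetrics]:
    df = pd.read_csv(path)
    out = []
    for _, r in df.iterrows():
        out.append(NightMetrics(
            child_id=str(r["child_id"]),
            night_date=date.fromisoformat(r["night_date"]),
            device=str(r["device"]),
            dialect=str(r["dialect"]),
            so=datetime.strptime(r["so"], _TS_FMT),
            fa=datetime.strptime(r["fa"], _TS_FMT),
            waso_min=float(r["waso_min"]),
            tst_min=float(r["tst_min"]),
            sol_min=None if pd.isna(r["sol_min"]) else float(r["sol_min"]),
            sol_outlier=bool(r["sol_outlier"]),
            quality_score=None if pd.isna(r["quality_score"])
            else float(r["quality_score"]),
            missing_frac=float(r["missing_frac"]),
            usable=bool(r["usable"]),
        ))
    return out
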