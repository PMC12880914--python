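#!/usr/bin/env python
"""Extract SO/FA/WASO/TST/SOL from every device-night.

The smartwatch stream is scored under the 5-min brief-wake-exclusion
dialect; the mat under the plain dialect; the EEG stream twice — by its
own single-channel algorithm and by the external majority-vote stager —
yielding two independent nightly estimates.
"""

from pathlib import Path

import pandas as pd

from sleepcohort.config import load_config
from sleepcohort.pipeline import stage_extract, stage_simulate

HERE = Path(__file__).resolve().parent

cfg = load_config(HERE / "config.yaml")
out = Path(cfg.out_dir)
_, _, recordings, _, _, _ = stage_simulate(cfg, out)  # deterministic regen
metrics = stage_extract(cfg, recordings, out)

df = pd.read_csv(out / "night_metrics.csv")
print(f"extracted {len(df)} device-nights "
      f"({df.child_id.nunique()} children, {df.device.nunique()} sources)")
print(df.groupby("device")[["tst_min", "waso_min"]].mean().round(1).to_string())
print(f"night metrics written to {out / 'night_metrics.csv'}")
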