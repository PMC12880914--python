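#!/usr/bin/env python
"""Harmonize nights, apply validity screens, select the analysis cohort.

Nights are labeled by final-awakening date; a night is valid when every
source shows TST 3-16 h starting 19:00-07:00, WASO <= 3 h, EEG quality
> 30, SOL <= 120 min. Children need >= 3 nights simultaneously valid on
all devices and the diary. Also reports the device-coverage Venn cells.
"""

import json
from pathlib import Path

import pandas as pd

from sleepcohort.config import load_config
from sleepcohort.io import read_metrics_csv
from sleepcohort.pipeline import stage_build_cohort

HERE = Path(__file__).resolve().parent

cfg = load_config(HERE / "config.yaml")
out = Path(cfg.out_dir)
metrics = read_metrics_csv(out / "night_metrics.csv")
diary = pd.read_csv(out / "diary.csv")
roster = pd.read_csv(out / "roster.csv")

table, selected, overlap = stage_build_cohort(cfg, metrics, diary, roster, out)

counts = pd.read_csv(out / "cohort_counts.csv")
print(f"all nights: {table.groupby(['child_id','night_date']).ngroups}; "
      f"retained rows: {len(selected)}")
print("children retained per group:")
print(counts.to_string(index=False))
print("device-coverage Venn cells:")
print(json.dumps(overlap["cells"], indent=2))
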