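#!/usr/bin/env python
"""Pairwise agreement (Lin's CCC + permutation significance) across sources.

Two matrices: per-night (devices + diary aligned on child x night) and
per-child (measures first averaged across each child's nights, with the
questionnaire's typical-night values added as a fifth source).
"""

from pathlib import Path

import pandas as pd

from sleepcohort.config import load_config
from sleepcohort.pipeline import stage_agreement

HERE = Path(__file__).resolve().parent

cfg = load_config(HERE / "config.yaml")
out = Path(cfg.out_dir)
selected = pd.read_csv(out / "analysis_cohort.csv")
behavior = pd.read_csv(out / "behavior.csv")

per_night, per_child = stage_agreement(cfg, selected, behavior, out)

for name, mat in (("per-night", per_night), ("per-child", per_child)):
    tst = mat[(mat.measure == "tst_min") & (mat.source_a < mat.source_b)]
    print(f"{name} TST concordance:")
    print(tst[["source_a", "source_b", "ccc", "p_value", "significant"]]
          .round(3).to_string(index=False))
print(f"matrices written to {out}/agreement_per_night.csv and "
      f"{out}/agreement_per_child.csv")
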