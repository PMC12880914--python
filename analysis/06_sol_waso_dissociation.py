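#!/usr/bin/env python
"""Sleep-onset vs sleep-maintenance dissociation against behavior scores.

Correlates per-child SOL and WASO (each EEG scoring route separately, then
their average) with every questionnaire scale, and compares the SOL vs
WASO correlations per scale with Steiger's Z for dependent correlations.
"""

from pathlib import Path

import pandas as pd

from sleepcohort.config import load_config
from sleepcohort.pipeline import stage_dissociation, stage_report

HERE = Path(__file__).resolve().parent

cfg = load_config(HERE / "config.yaml")
out = Path(cfg.out_dir)
selected = pd.read_csv(out / "analysis_cohort.csv")
behavior = pd.read_csv(out / "behavior.csv")

report = stage_dissociation(cfg, selected, behavior, out)

mm = report["mean_matrix"]
print("averaged-estimate correlations (r, * = p<0.05 uncorrected):")
piv = mm.assign(cell=mm.apply(
    lambda r: f"{r['r']:+.2f}{'*' if r['significant'] else ' '}", axis=1)) \
    .pivot(index="sleep_measure", columns="scale", values="cell")
print(piv.to_string())
st = report["steiger"]
print("\nSteiger Z (SOL vs WASO correlation, per scale):")
print(st[["scale", "r_sol", "r_waso", "z", "p", "significant"]]
      .round(3).to_string(index=False))
n_sig = int(st.significant.sum())
print(f"\nSOL correlations significantly stronger than WASO for "
      f"{n_sig}/{len(st)} scales")

if cfg.make_figures:
    per_night = pd.read_csv(out / "agreement_per_night.csv")
    per_child = pd.read_csv(out / "agreement_per_child.csv")
    models = pd.read_csv(out / "mixed_models.csv")
    stage_report(cfg, out, per_night, per_child, models, report)
    print(f"figures written to {out}/")
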