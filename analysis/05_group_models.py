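#!/usr/bin/env python
"""Autism-sibling contrasts with family random-intercept mixed models.

Per-night TST and WASO from each source, SOL from the EEG stream, and the
per-child questionnaire scores, each modeled as
outcome ~ diagnosis + age + sex + (1 | family); reports the diagnosis
beta, its p, the family ICC and Cohen's f2.
"""

from pathlib import Path

import pandas as pd

from sleepcohort.config import load_config
from sleepcohort.pipeline import stage_models

HERE = Path(__file__).resolve().parent

cfg = load_config(HERE / "config.yaml")
out = Path(cfg.out_dir)
selected = pd.read_csv(out / "analysis_cohort.csv")
roster = pd.read_csv(out / "roster.csv")
behavior = pd.read_csv(out / "behavior.csv")

models = stage_models(cfg, selected, roster, behavior, out)

show = models[["outcome", "beta_diagnosis", "se_diagnosis", "p_diagnosis",
               "icc", "f2_diagnosis"]].round(3)
print(show.to_string(index=False))
sol = models[models.outcome == "sol_min[eeg]"]
if len(sol):
    r = sol.iloc[0]
    print(f"\nSOL contrast: autistic children fall asleep "
          f"{r.beta_diagnosis:+.1f} min later (SE {r.se_diagnosis:.1f}, "
          f"p={r.p_diagnosis:.3g})")
print(f"model table written to {out / 'mixed_models.csv'}")
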