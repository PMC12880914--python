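#!/usr/bin/env python
"""Generate the synthetic family-paired cohort and write its source tables.

Produces the roster (one autistic child + one non-autistic sibling per
family), the latent per-night ground truth, the parent diary, behavior
questionnaire scores, and — kept in memory by later stages — the per-night
epoch-level device recordings.
"""

from pathlib import Path

from sleepcohort.config import load_config
from sleepcohort.pipeline import stage_simulate

HERE = Path(__file__).resolve().parent

cfg = load_config(HERE / "config.yaml")
out = Path(cfg.out_dir)
out.mkdir(parents=True, exist_ok=True)

roster, truth, recordings, diary, behavior, _ = stage_simulate(cfg, out)

n_aut = (roster.diagnosis == "autism").sum()
print(f"cohort: {len(roster)} children ({n_aut} autistic, "
      f"{len(roster) - n_aut} siblings) in {roster.family_id.nunique()} families")
print(f"latent nights: {len(truth)}; device recordings: {len(recordings)}")
print(f"mean latent SOL by group:\n"
      f"{truth.groupby('diagnosis')['sol_min'].mean().round(1).to_string()}")
print(f"tables written to {out}/")
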