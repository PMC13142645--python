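#!/usr/bin/env python
"""Case-control difference in the brain-age gap through the full pipeline.

Injects a +0.6 SD case shift (calibrated against the pipeline's own BAG
dispersion), then estimates the diagnosis effect on residualized,
z-scored BAG with HC3 robust SEs and site fixed effects, plus per-site
Welch contrasts.  Writes results/group_difference.csv and
results/per_site_welch.csv.
"""

from pathlib import Path

import pandas as pd

from fcbag import brainage
from fcbag.synthetic import SyntheticConfig
from fcbag.workflow import RunConfig, calibrated_group_analysis

OUT = Path(__file__).resolve().parents[1] / "results"

cfg = RunConfig(
    cohort=SyntheticConfig(n_subjects=400, seed=1),
    seed=1, families=["ridge", "svr_rbf"],
    cv=brainage.CVSpec(outer_folds=5, outer_repeats=2, inner_folds=3,
                       search_budget=8, seed=1),
)
run = calibrated_group_analysis(cfg, target_shift_sd=0.6)
g = run["stats_group"]

OUT.mkdir(exist_ok=True)
pd.DataFrame([g.__dict__]).round(4).to_csv(OUT / "group_difference.csv", index=False)
run["stats_per_site"].round(4).to_csv(OUT / "per_site_welch.csv", index=False)

print(f"Control residualized-BAG dispersion: {run['sigma_years']:.2f} years; "
      f"injected case shift {run['bag_shift_years']:.2f} years (0.6 SD).")
print(f"Diagnosis effect on BAG z-score: beta = {g.beta:.2f} "
      f"(95% CI {g.ci_low:.2f} to {g.ci_high:.2f}, p = {g.p_two_sided:.2g}, "
      f"n = {g.n} matched subjects).")
print("\nPer-site Welch contrasts (within-site z-scores):")
print(run["stats_per_site"][["site", "welch_t", "welch_df", "p",
                             "cohens_d", "hedges_g"]].round(3).to_string(index=False))
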