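#!/usr/bin/env python
"""Longitudinal coupling between BAG change and clinical change.

Generates a follow-up visit for an all-SSD cohort with generator
coupling 0.5 between the true BAG change (baseline - follow-up) and
clinical change scores, then fits HC3 regressions of the BAG delta on
each clinical delta (rank-INT within visit).  Writes
results/longitudinal_associations.csv.
"""

from pathlib import Path

from fcbag import stats
from fcbag.synthetic import SyntheticConfig, generate_cohort, generate_followup

OUT = Path(__file__).resolve().parents[1] / "results"
VARS = ["nss_total", "nss_moco", "nss_hs", "panss_total", "dsst"]

cfg = SyntheticConfig(n_subjects=300, n_regions=12, n_timepoints=80,
                      case_fraction=1.0, longitudinal=True, seed=1)
base = generate_cohort(cfg)
fu = generate_followup(base, delta_bag_mean=0.0, coupling=0.5)


def frame(cohort):
    t = cohort.truth["subjects"][["subject_id", "true_bag"]].rename(
        columns={"true_bag": "bag"})
    return t.merge(cohort.metadata[["subject_id"] + VARS], on="subject_id")


deltas = stats.longitudinal_delta(frame(base), frame(fu), VARS)
table = stats.delta_associations(deltas, VARS)

OUT.mkdir(exist_ok=True)
table.round(4).to_csv(OUT / "longitudinal_associations.csv", index=False)

print("BAG delta (years, baseline - follow-up) per 1 SD of clinical delta:")
print(table[["predictor", "beta", "ci_low", "ci_high", "p_two_sided",
             "q_fdr", "n"]].round(3).to_string(index=False))
print("\nNegative betas on symptom deltas: an increase in BAG over the "
      "follow-up interval accompanies a decrease in symptom scores, as "
      "injected by the generator's coupling of 0.5.")
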