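"""Stratified cohort summary: counts, mean scores and category breakdown.

Summarises a dual-rated synthetic cohort by centre, trial type and phase.
Each trial enters once, represented by its first-listed rater's score
(rule "rater_a"); pass per_trial_rule="per_score" to summarise all 120
scores instead.
"""

import pandas as pd

from pharmcat import (
    default_study_config,
    generate_cohort,
    score_cohort,
    study_cutoffs,
    summarize_cohort,
)

cohort = generate_cohort(default_study_config(seed=7))
records = score_cohort(cohort.assessments)
summary = summarize_cohort(records, study_cutoffs(), per_trial_rule="rater_a")

df = pd.DataFrame(summary.to_rows())
print(df.to_string(index=False))
# Every stratum row shows its trial count, share of the cohort, mean
# complexity score and the within-stratum low/medium/high percentages;
# phase I trials score highest (the phase item alone adds two points).
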