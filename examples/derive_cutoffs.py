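"""Derive tertile cut-offs from a cohort of scores.

Generates a synthetic 60-trial cohort (120 scores), sorts the totals and
takes the order statistics at ranks ceil(n/3) and ceil(2n/3) as the
category boundaries — the same construction the published cut-offs
(19, 25) came from.
"""

from pharmcat import (
    default_study_config,
    derive_cutoffs,
    generate_cohort,
    score_cohort,
    study_cutoffs,
)

cohort = generate_cohort(default_study_config(seed=7))
records = score_cohort(cohort.assessments)
totals = [r.total for r in records]

cuts = derive_cutoffs(totals)
ref = study_cutoffs()
print(f"scores: n={len(totals)}, range {min(totals)}-{max(totals)}")
print(f"derived cut-offs:  low <= {cuts.low_max} < medium <= {cuts.med_max} < high")
print(f"published cut-offs: low <= {ref.low_max} < medium <= {ref.med_max} < high")
# The derived boundaries are observed scores near the published ones; they
# differ by a point or two because the synthetic cohort is not the real one.
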