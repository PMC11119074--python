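"""Score a single trial assessment and assign its complexity category.

Builds one completed 15-item form for a phase III oncology trial, checks
it against the instrument, sums the item scores and maps the total onto
the published low/medium/high cut-offs.
"""

from pharmcat import (
    Assessment,
    ItemResponse,
    categorize,
    default_instrument,
    study_cutoffs,
    total_score,
    validate_assessment,
)

inst = default_instrument()

# items 1..15: phase III (1), injectable (3), IWRS supply chain (2),
# 2 drugs (2), 2-3 days/cycle (2), standard staff (2), one storage mode (1),
# no special devices (1), no relabelling (1), returned-drug accountability (3),
# automatic resupply (1), double-blind (2), personalised dose (2),
# no special preparation (0), no personalised administration (0)
scores = (1, 3, 2, 2, 2, 2, 1, 1, 1, 3, 1, 2, 2, 0, 0)

assessment = Assessment(
    trial_id="EXAMPLE-01",
    centre_id="centre_1",
    trial_type="oncology",
    phase="III",
    rater_id="A",
    responses=tuple(ItemResponse(item_id=i + 1, score=s) for i, s in enumerate(scores)),
)

violations = validate_assessment(assessment, inst)
print(f"violations: {violations!r}")

result = total_score(assessment, inst)
category = categorize(result.total, study_cutoffs())
print(f"total score: {result.total} (possible range 15-44)")
print(f"complexity category: {category} (low <= 19 < medium <= 25 < high)")
# A 23-point trial sits in the medium tertile of the development cohort:
# a typical double-blind injectable phase III study.
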