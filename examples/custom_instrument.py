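"""Adapt the instrument to a local pharmacy service.

Instruments are data, not code: a service can drop items that do not
apply and add its own, then score assessments against the modified
config.  Here a 3-item mini instrument is defined inline and scored.
"""

from pharmcat import (
    Assessment,
    ItemResponse,
    achievable_totals,
    load_instrument,
    score_bounds,
    total_score,
)

config = {
    "name": "mini service instrument",
    "items": [
        {"item_id": 1, "section": "study_design", "label": "Study phase",
         "levels": [{"score": 1, "description": "phase II or phase III"},
                    {"score": 3, "description": "phase I"}]},
        {"item_id": 2, "section": "drug_management", "label": "Hazardous handling",
         "levels": [{"score": 0, "description": "no"},
                    {"score": 2, "description": "yes"}]},
        {"item_id": 3, "section": "drug_preparation", "label": "Dose preparation",
         "levels": [{"score": 1, "description": "ready to use"},
                    {"score": 2, "description": "personalised dose"},
                    {"score": 3, "description": "reconstitution + personalised dose"}]},
    ],
}

inst = load_instrument(config)
print(f"instrument: {inst.name!r}, {len(inst.items)} items")
print(f"score bounds: {score_bounds(inst)}")
print(f"achievable totals: {sorted(achievable_totals(inst))}")

assessment = Assessment(
    trial_id="LOCAL-1", centre_id="c1", trial_type="haematology", phase="I",
    rater_id="A",
    responses=(ItemResponse(item_id=1, score=3),
               ItemResponse(item_id=2, score=2),
               ItemResponse(item_id=3, score=2)),
)
print(f"total: {total_score(assessment, inst).total}")
# Here every integer between the bounds happens to be reachable; with more
# strongly gapped level sets some totals in between are not, which is why
# achievable_totals exists alongside score_bounds.
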