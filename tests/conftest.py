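import itertools

import pytest
from hypothesis import HealthCheck, settings

from pharmcat import (
    Assessment,
    Instrument,
    ItemDefinition,
    ItemResponse,
    Phase,
    ScoreLevel,
    Section,
    TrialType,
    default_instrument,
)

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def inst() -> Instrument:
    return default_instrument()


def make_instrument(level_sets, name="custom") -> Instrument:
    """Instrument from a list of per-item allowed-score sets."""
    sections = list(Section)
    items = [
        ItemDefinition(
            item_id=i + 1,
            section=sections[i % 3],
            label=f"item {i + 1}",
            levels=tuple(ScoreLevel(score=s, description=f"level {s}") for s in sorted(levels)),
        )
        for i, levels in enumerate(level_sets)
    ]
    return Instrument(name=name, items=tuple(items))


def make_assessment(scores, trial_id="T1", rater_id="A", centre_id="centre_1",
                    trial_type=TrialType.oncology, phase=None) -> Assessment:
    """Default-instrument assessment from 15 item scores (items 1..15).

    Unless given, the phase is inferred from item 1 so the assessment is
    phase-consistent by construction.
    """
    if phase is None:
        phase = Phase.I if scores[0] == 3 else Phase.III
    return Assessment(
        trial_id=trial_id,
        centre_id=centre_id,
        trial_type=trial_type,
        phase=phase,
        rater_id=rater_id,
        responses=tuple(
            ItemResponse(item_id=i + 1, score=s) for i, s in enumerate(scores)
        ),
    )


def enumerate_totals(instrument: Instrument) -> set:
    """Brute-force oracle: totals over every admissible level combination."""
    level_sets = [sorted(it.allowed_scores) for it in instrument.items]
    return {sum(combo) for combo in itertools.product(*level_sets)}


# per-item minimum/maximum response profiles for the default instrument
MIN_PROFILE = (1, 2, 1, 1, 1, 2, 1, 1, 1, 1, 1, 1, 1, 0, 0)   # sums to 15
MAX_PROFILE = (3, 3, 3, 3, 3, 3, 3, 2, 3, 3, 3, 3, 3, 3, 3)   # sums to 44
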