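"""The Pharm-CAT instrument: item definitions, assessments and total scores.

Pharm-CAT scores the complexity of pharmacy involvement in a sponsored
oncology or haematology clinical trial.  It is a 15-item checklist grouped
into three sections — study design, drug management and drug preparation —
where each item offers a small fixed set of scored levels (0–3 points) and
the trial's complexity score is simply the sum of the item scores.  The
default instrument spans totals from 15 to 44 points.

Instruments are pure data.  The default 15-item instrument ships as a
packaged JSON config (``data/pharm_cat_v1.json``) and any modified
instrument — items added, removed or re-levelled for a particular pharmacy
service — can be loaded from a config of the same shape with
:func:`load_instrument`; no code change is required.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from enum import Enum
from functools import lru_cache
from importlib import resources
from pathlib import Path
from typing import Union

import pydantic
from pydantic import BaseModel, ConfigDict, Field, field_validator

from .errors import AssessmentValidationError, InstrumentSchemaError

__all__ = [
    "Section",
    "TrialType",
    "Phase",
    "ScoreLevel",
    "ItemDefinition",
    "Instrument",
    "ItemResponse",
    "Assessment",
    "ScoreResult",
    "Violation",
    "default_instrument",
    "load_instrument",
    "validate_assessment",
    "total_score",
    "score_bounds",
    "achievable_totals",
]


class Section(str, Enum):
    """The three sections of the instrument."""

    study_design = "study_design"
    drug_management = "drug_management"
    drug_preparation = "drug_preparation"


class TrialType(str, Enum):
    oncology = "oncology"
    haematology = "haematology"


class Phase(str, Enum):
    I = "I"
    II = "II"
    III = "III"


class ScoreLevel(BaseModel):
    """One selectable level of an item: a score and what it stands for."""

    model_config = ConfigDict(frozen=True)

    score: int = Field(ge=0, le=3)
    description: str


class ItemDefinition(BaseModel):
    """A single instrument item with its allowed scored levels."""

    model_config = ConfigDict(frozen=True)

    item_id: int = Field(ge=1)
    section: Section
    label: str
    levels: tuple[ScoreLevel, ...] = Field(min_length=2)

    @field_validator("levels")
    @classmethod
    def _distinct_scores(cls, v: tuple[ScoreLevel, ...]) -> tuple[ScoreLevel, ...]:
        scores = [lev.score for lev in v]
        if len(set(scores)) != len(scores):
            raise ValueError(f"duplicate level scores {scores}")
        return v

    @property
    def allowed_scores(self) -> frozenset[int]:
        return frozenset(lev.score for lev in self.levels)

    @property
    def min_score(self) -> int:
        return min(self.allowed_scores)

    @property
    def max_score(self) -> int:
        return max(self.allowed_scores)


class Instrument(BaseModel):
    """An ordered collection of items; the scoring universe for assessments."""

    model_config = ConfigDict(frozen=True)

    name: str
    items: tuple[ItemDefinition, ...] = Field(min_length=1)

    @field_validator("items")
    @classmethod
    def _unique_ids(cls, v: tuple[ItemDefinition, ...]) -> tuple[ItemDefinition, ...]:
        ids = [it.item_id for it in v]
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        if dupes:
            raise ValueError(f"duplicate item_id {dupes}")
        return v

    def item(self, item_id: int) -> ItemDefinition:
        for it in self.items:
            if it.item_id == item_id:
                return it
        raise KeyError(f"no item {item_id} in instrument {self.name!r}")

    @property
    def item_ids(self) -> tuple[int, ...]:
        return tuple(it.item_id for it in self.items)


class ItemResponse(BaseModel):
    model_config = ConfigDict(frozen=True)

    item_id: int
    score: int


class Assessment(BaseModel):
    """One rater's complete set of item responses for one trial."""

    model_config = ConfigDict(frozen=True)

    trial_id: str
    centre_id: str
    trial_type: TrialType
    phase: Phase
    rater_id: str
    responses: tuple[ItemResponse, ...]

    def response_map(self) -> dict[int, int]:
        return {r.item_id: r.score for r in self.responses}


@dataclass(frozen=True)
class ScoreResult:
    trial_id: str
    rater_id: str
    total: int


@dataclass(frozen=True)
class Violation:
    """One way in which an assessment fails the instrument's rules.

    Violations are data, not exceptions: ``validate_assessment`` returns all
    of them at once so a data-entry problem can be reported in full.
    """

    item_id: Union[int, None]
    reason: str

    def __str__(self) -> str:
        prefix = f"item {self.item_id}: " if self.item_id is not None else ""
        return prefix + self.reason


@lru_cache(maxsize=1)
def default_instrument() -> Instrument:
    """The packaged 15-item Pharm-CAT instrument.

    Level sets per item: items 3, 4, 5, 7, 12 and 13 offer 1/2/3 points;
    item 1 (study phase) 1 or 3; items 2 and 6 offer 2/3; item 8 offers 1/2;
    items 9, 10 and 11 offer 1/3; item 14 offers 0/2/3; item 15 offers 0/3.
    """
    text = resources.files("pharmcat.data").joinpath("pharm_cat_v1.json").read_text("utf-8")
    return load_instrument(json.loads(text))


def load_instrument(config: Union[dict, str, Path]) -> Instrument:
    """Build an :class:`Instrument` from a config document.

    Parameters
    ----------
    config
        Either an already-parsed mapping with keys ``name`` and ``items``,
        or a path to a JSON file containing one.

    Raises
    ------
    InstrumentSchemaError
        If the document is malformed; the message names the offending field.
    """
    if isinstance(config, (str, Path)):
        try:
            config = json.loads(Path(config).read_text("utf-8"))
        except json.JSONDecodeError as exc:
            raise InstrumentSchemaError(f"not valid JSON: {exc}") from exc
    if not isinstance(config, dict):
        raise InstrumentSchemaError(f"instrument config must be a mapping, got {type(config).__name__}")
    try:
        return Instrument.model_validate(config)
    except pydantic.ValidationError as exc:
        details = "; ".join(
            f"{'.'.join(str(p) for p in err['loc']) or '<root>'}: {err['msg']}"
            for err in exc.errors()
        )
        raise InstrumentSchemaError(f"invalid instrument config: {details}") from exc


def _phase_item(inst: Instrument) -> Union[ItemDefinition, None]:
    """The study-phase item, if this instrument carries it in default form.

    Item 1 of the default instrument is fully determined by the trial phase
    (3 points for phase I, 1 otherwise).  The cross-field check only makes
    sense when item 1 still has exactly the {1, 3} level set; a modified
    instrument with a different item 1 opts out automatically.
    """
    try:
        it = inst.item(1)
    except KeyError:
        return None
    return it if it.allowed_scores == frozenset({1, 3}) else None


def validate_assessment(
    assessment: Assessment,
    instrument: Union[Instrument, None] = None,
    *,
    check_phase_item: bool = True,
) -> list[Violation]:
    """Check an assessment against an instrument; return all violations.

    An empty list means the assessment is valid: exactly one response per
    instrument item, every score drawn from the item's allowed levels, and
    (unless ``check_phase_item=False``) the study-phase item consistent with
    the trial's phase.
    """
    inst = instrument or default_instrument()
    violations: list[Violation] = []

    seen: dict[int, list[int]] = {}
    for resp in assessment.responses:
        seen.setdefault(resp.item_id, []).append(resp.score)

    known_ids = set(inst.item_ids)
    for item_id, scores in seen.items():
        if item_id not in known_ids:
            violations.append(Violation(item_id, "not an instrument item"))
        elif len(scores) > 1:
            violations.append(Violation(item_id, f"{len(scores)} responses for one item"))

    for item in inst.items:
        scores = seen.get(item.item_id)
        if scores is None:
            violations.append(Violation(item.item_id, f"missing item {item.item_id}"))
            continue
        allowed = sorted(item.allowed_scores)
        for s in scores:
            if s not in item.allowed_scores:
                violations.append(
                    Violation(item.item_id, f"score {s} not in {{{','.join(map(str, allowed))}}}")
                )

    if check_phase_item:
        phase_item = _phase_item(inst)
        if phase_item is not None and phase_item.item_id in seen and len(seen[phase_item.item_id]) == 1:
            expected = 3 if assessment.phase is Phase.I else 1
            actual = seen[phase_item.item_id][0]
            if actual in phase_item.allowed_scores and actual != expected:
                violations.append(
                    Violation(
                        phase_item.item_id,
                        f"score {actual} inconsistent with phase {assessment.phase.value}"
                        f" (expected {expected})",
                    )
                )

    return violations


def total_score(
    assessment: Assessment,
    instrument: Union[Instrument, None] = None,
    *,
    check_phase_item: bool = True,
) -> ScoreResult:
    """Sum the item scores of a valid assessment.

    Raises :class:`AssessmentValidationError` (listing every violation) if
    the assessment does not validate against the instrument.
    """
    inst = instrument or default_instrument()
    violations = validate_assessment(assessment, inst, check_phase_item=check_phase_item)
    if violations:
        raise AssessmentValidationError(violations)
    total = sum(r.score for r in assessment.responses)
    return ScoreResult(trial_id=assessment.trial_id, rater_id=assessment.rater_id, total=total)


def score_bounds(instrument: Union[Instrument, None] = None) -> tuple[int, int]:
    """Minimum and maximum achievable total (sum of per-item minima/maxima).

    Because items score independently, the extreme totals are attained by
    taking every item at its extreme level; for the default instrument this
    gives (15, 44).
    """
    inst = instrument or default_instrument()
    return (
        sum(it.min_score for it in inst.items),
        sum(it.max_score for it in inst.items),
    )


def achievable_totals(instrument: Union[Instrument, None] = None) -> frozenset[int]:
    """Every total reachable by some admissible response combination.

    Computed by dynamic programming over items (subset-sum style), so the
    cost is linear in the number of items times the score range rather than
    exponential in the number of items.  Not every integer between the score
    bounds is necessarily reachable for an arbitrary instrument.
    """
    inst = instrument or default_instrument()
    totals: set[int] = {0}
    for item in inst.items:
        totals = {t + s for t in totals for s in item.allowed_scores}
    return frozenset(totals)
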