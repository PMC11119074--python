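"""Stratified cohort summaries: counts, percentages, mean scores, categories.

Reproduces the shape of the development study's results table: one row for
the whole cohort, then rows per centre, per trial type and per phase, each
with the number of trials, its share of the cohort, the mean complexity
score and the low/medium/high category breakdown (percentages computed
within the stratum).

When every trial carries two independent scores, one value per trial must
be chosen before categorising.  How the original study collapsed its dual
scores is unknown, so the rule is explicit and selectable:

* ``rater_a`` (default) — the first-listed rater's score;
* ``mean_floor`` — floor of the two raters' mean;
* ``max`` — the higher of the two scores;
* ``per_score`` — no collapsing: every score is its own unit, so n counts
  scores rather than trials (the mode in which a 60-trial dual-rated
  cohort summarises 120 scores).

Percentages and means are rounded half-up to 2 decimals for display.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Union

from ._utils import round_half_up
from .categorization import ComplexityCategory, CutoffSet, categorize
from .errors import InsufficientDataError
from .instrument import Phase, TrialType, total_score
from .io import ScoreRecord

__all__ = [
    "PER_TRIAL_RULES",
    "StratumSummary",
    "CohortSummary",
    "score_cohort",
    "summarize_cohort",
]

PER_TRIAL_RULES = ("rater_a", "mean_floor", "max", "per_score")


@dataclass(frozen=True)
class StratumSummary:
    stratum_kind: str   # "total" | "centre" | "type" | "phase"
    stratum: str
    n_trials: int
    percent_of_cohort: float
    mean_score: float
    n_low: int
    pct_low: float
    n_med: int
    pct_med: float
    n_high: int
    pct_high: float


@dataclass(frozen=True)
class CohortSummary:
    strata: tuple[StratumSummary, ...]

    @property
    def total(self) -> StratumSummary:
        return self.strata[0]

    def to_rows(self) -> list[dict]:
        return [vars(s).copy() for s in self.strata]


def score_cohort(assessments, instrument=None, cutoffs: Union[CutoffSet, None] = None) -> list[ScoreRecord]:
    """Score every assessment and attach metadata (and category, if cut-offs given)."""
    records = []
    for a in assessments:
        res = total_score(a, instrument)
        records.append(
            ScoreRecord(
                trial_id=a.trial_id,
                centre_id=a.centre_id,
                trial_type=a.trial_type,
                phase=a.phase,
                rater_id=a.rater_id,
                total=res.total,
                category=None if cutoffs is None else categorize(res.total, cutoffs),
            )
        )
    return records


def _collapse(records: list[ScoreRecord], rule: str) -> list[ScoreRecord]:
    """One ScoreRecord per analysis unit according to the per-trial rule."""
    if rule == "per_score":
        return list(records)
    by_trial: dict[str, list[ScoreRecord]] = {}
    for r in records:
        by_trial.setdefault(r.trial_id, []).append(r)
    collapsed = []
    for trial_id, group in by_trial.items():
        if rule == "rater_a":
            chosen = group[0]
            total = chosen.total
        else:
            if len(group) != 2:
                raise ValueError(
                    f"trial {trial_id!r} has {len(group)} scores; rule {rule!r} needs exactly 2"
                )
            a, b = group[0].total, group[1].total
            total = (a + b) // 2 if rule == "mean_floor" else max(a, b)
            chosen = group[0]
        collapsed.append(
            ScoreRecord(
                trial_id=chosen.trial_id,
                centre_id=chosen.centre_id,
                trial_type=chosen.trial_type,
                phase=chosen.phase,
                rater_id=chosen.rater_id,
                total=total,
            )
        )
    return collapsed


def _unit_key(r: ScoreRecord) -> tuple[str, str]:
    return (r.trial_id, r.rater_id)


def _summarise_stratum(kind: str, label: str, records: list[ScoreRecord],
                       cats: dict, n_cohort: int) -> StratumSummary:
    n = len(records)
    counts = {c: 0 for c in ComplexityCategory}
    for r in records:
        counts[cats[_unit_key(r)]] += 1
    return StratumSummary(
        stratum_kind=kind,
        stratum=label,
        n_trials=n,
        percent_of_cohort=round_half_up(100.0 * n / n_cohort, 2),
        mean_score=round_half_up(sum(r.total for r in records) / n, 2),
        n_low=counts[ComplexityCategory.low],
        pct_low=round_half_up(100.0 * counts[ComplexityCategory.low] / n, 2),
        n_med=counts[ComplexityCategory.medium],
        pct_med=round_half_up(100.0 * counts[ComplexityCategory.medium] / n, 2),
        n_high=counts[ComplexityCategory.high],
        pct_high=round_half_up(100.0 * counts[ComplexityCategory.high] / n, 2),
    )


def summarize_cohort(
    records: list[ScoreRecord],
    cutoffs: Union[CutoffSet, None] = None,
    per_trial_rule: str = "rater_a",
) -> CohortSummary:
    """Build the stratified summary (total, per centre, per type, per phase).

    ``records`` are per-(trial, rater) scores with metadata; they are first
    collapsed to one value per analysis unit via ``per_trial_rule``, then
    categorised with ``cutoffs`` (default: the published study cut-offs).
    """
    if not records:
        raise InsufficientDataError("summarize_cohort needs at least one score")
    if per_trial_rule not in PER_TRIAL_RULES:
        raise ValueError(f"unknown per_trial_rule {per_trial_rule!r}; choose from {PER_TRIAL_RULES}")

    units = _collapse(records, per_trial_rule)
    cats = {_unit_key(u): categorize(u.total, cutoffs) for u in units}
    n_cohort = len(units)

    strata = [_summarise_stratum("total", "total", units, cats, n_cohort)]
    for centre in sorted({u.centre_id for u in units}):
        strata.append(_summarise_stratum(
            "centre", centre, [u for u in units if u.centre_id == centre], cats, n_cohort))
    for ttype in sorted(TrialType, key=lambda t: t.value):
        sub = [u for u in units if u.trial_type is ttype]
        if sub:
            strata.append(_summarise_stratum("type", ttype.value, sub, cats, n_cohort))
    for phase in Phase:
        sub = [u for u in units if u.phase is phase]
        if sub:
            strata.append(_summarise_stratum("phase", phase.value, sub, cats, n_cohort))
    return CohortSummary(strata=tuple(strata))
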