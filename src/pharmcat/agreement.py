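"""Inter-rater reproducibility of paired complexity assessments.

Two pharmacists score every trial independently; reproducibility is
summarised four ways:

* exact-score concordance — the percentage of trials where both raters
  produce the same total;
* the distribution and mean of absolute score differences;
* the 3x3 cross-classification of complexity categories (rater A rows,
  rater B columns);
* Cohen's linear weighted kappa on that cross-classification.

Kappa uses linear *disagreement* weights ``w(i, j) = |i - j| / (k - 1)``
and the form ``kappa = 1 - sum(w * p_obs) / sum(w * p_exp)`` with expected
proportions from the margins' product.  The equivalent agreement-weight
formulation (weights ``1 - |i - j|/(k - 1)`` plugged into the unweighted
kappa formula) gives identical values.

By default kappa is computed on the three complexity categories, the scale
on which the instrument is used once cut-offs exist.  For sensitivity
analysis :func:`raw_score_kappa` treats every observed total as its own
ordinal level instead.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from ._utils import round_half_up
from .categorization import ComplexityCategory, CutoffSet, categorize
from .errors import InsufficientDataError, UndefinedKappaError

__all__ = [
    "PairedScores",
    "CrossClassification",
    "AgreementReport",
    "pair_scores",
    "score_diff_summary",
    "cross_classification",
    "linear_weighted_kappa",
    "raw_score_kappa",
    "agreement_report",
]


@dataclass(frozen=True)
class PairedScores:
    """Rater A's and rater B's totals for the same trial."""

    trial_id: str
    total_a: int
    total_b: int


@dataclass(frozen=True)
class CrossClassification:
    """3x3 category table; rows rater A, columns rater B, order low/medium/high."""

    counts: tuple[tuple[int, int, int], ...]
    n: int

    def __post_init__(self) -> None:
        arr = np.asarray(self.counts)
        if arr.shape != (3, 3):
            raise ValueError(f"cross-classification must be 3x3, got {arr.shape}")
        if (arr < 0).any():
            raise ValueError("cross-classification counts must be non-negative")
        if int(arr.sum()) != self.n or self.n < 1:
            raise ValueError(f"counts sum to {int(arr.sum())} but n = {self.n} (need n >= 1)")

    @classmethod
    def from_array(cls, counts) -> "CrossClassification":
        arr = np.asarray(counts, dtype=int)
        return cls(counts=tuple(tuple(int(x) for x in row) for row in arr), n=int(arr.sum()))

    def to_array(self) -> np.ndarray:
        return np.asarray(self.counts, dtype=float)

    @property
    def diagonal_count(self) -> int:
        return int(np.trace(np.asarray(self.counts)))


@dataclass(frozen=True)
class AgreementReport:
    """All paired-rater reproducibility statistics in one record."""

    n_trials: int
    n_exact: int
    percent_exact: float          # 2-decimal display value
    diff_histogram: dict[int, int]
    mean_abs_diff: float          # 2-decimal display value
    cross_class: CrossClassification
    same_category_count: int
    weighted_kappa: float | None  # None when undefined (single-cell table)
    kappa_defined: bool = True
    _exact_mean_abs_diff: float = field(default=0.0, repr=False, compare=False)

    def to_dict(self) -> dict:
        return {
            "n_trials": self.n_trials,
            "n_exact": self.n_exact,
            "percent_exact": self.percent_exact,
            "percent_exact_0dp": round_half_up(self.percent_exact, 0),
            "diff_histogram": {str(k): v for k, v in sorted(self.diff_histogram.items())},
            "mean_abs_diff": self.mean_abs_diff,
            "cross_classification": [list(row) for row in self.cross_class.counts],
            "same_category_count": self.same_category_count,
            "weighted_kappa": self.weighted_kappa,
            "kappa_defined": self.kappa_defined,
        }


def pair_scores(scores) -> list[PairedScores]:
    """Group per-rater ScoreResults into PairedScores, one per trial.

    Requires exactly two raters per trial; rater A is the first-listed
    rater for that trial (input order is preserved).
    """
    by_trial: dict[str, list] = {}
    for s in scores:
        by_trial.setdefault(s.trial_id, []).append(s)
    pairs = []
    for trial_id, group in by_trial.items():
        if len(group) != 2:
            raise ValueError(f"trial {trial_id!r} has {len(group)} scores; paired analysis needs exactly 2")
        pairs.append(PairedScores(trial_id=trial_id, total_a=group[0].total, total_b=group[1].total))
    return pairs


def score_diff_summary(pairs: list[PairedScores]) -> tuple[float, dict[int, int], float]:
    """Percent of exactly-matching pairs, |difference| histogram, mean |difference|.

    Percent and mean are rounded half-up to 2 decimals for reporting; the
    histogram is exact.
    """
    if not pairs:
        raise InsufficientDataError("score_diff_summary needs at least one pair")
    n = len(pairs)
    diffs = [abs(p.total_a - p.total_b) for p in pairs]
    hist = dict(sorted(Counter(diffs).items()))
    n_exact = hist.get(0, 0)
    percent_exact = round_half_up(100.0 * n_exact / n, 2)
    mean_abs = round_half_up(sum(diffs) / n, 2)
    return percent_exact, hist, mean_abs


def cross_classification(pairs: list[PairedScores], cutoffs: CutoffSet | None = None) -> CrossClassification:
    """Tabulate rater A's vs rater B's complexity category over all pairs."""
    if not pairs:
        raise InsufficientDataError("cross_classification needs at least one pair")
    counts = np.zeros((3, 3), dtype=int)
    for p in pairs:
        i = categorize(p.total_a, cutoffs)
        j = categorize(p.total_b, cutoffs)
        counts[i, j] += 1
    return CrossClassification.from_array(counts)


def _weighted_kappa(counts: np.ndarray) -> float:
    """Linear weighted kappa for a square ordinal contingency table."""
    counts = np.asarray(counts, dtype=float)
    k = counts.shape[0]
    n = counts.sum()
    if n < 1:
        raise InsufficientDataError("kappa needs at least one pair")
    idx = np.arange(k)
    w = np.abs(idx[:, None] - idx[None, :]) / (k - 1)
    p_obs = counts / n
    row = counts.sum(axis=1)
    col = counts.sum(axis=0)
    p_exp = np.outer(row, col) / n**2
    denom = float((w * p_exp).sum())
    if denom == 0.0:
        # every pair in a single identical category: agreement is perfect
        # but there is no disagreement to correct for chance
        raise UndefinedKappaError(
            "weighted kappa undefined: all mass in one category for both raters",
            perfect_agreement=True,
        )
    return 1.0 - float((w * p_obs).sum()) / denom


def linear_weighted_kappa(table: CrossClassification | np.ndarray) -> float:
    """Cohen's linear weighted kappa for a cross-classification.

    Result is at most 1 (attained iff all mass lies on the diagonal) and 0
    when observed agreement equals what the margins predict by chance.

    Raises :class:`UndefinedKappaError` (with ``perfect_agreement=True``)
    when both raters put every trial in the same single category, making
    the chance-disagreement denominator zero.
    """
    counts = table.to_array() if isinstance(table, CrossClassification) else np.asarray(table)
    return _weighted_kappa(counts)


def raw_score_kappa(pairs: list[PairedScores]) -> float:
    """Linear weighted kappa treating each observed total as an ordinal level.

    Sensitivity analysis: the levels are the sorted distinct totals seen in
    the data, so the weight between two totals reflects their rank distance,
    not the point difference.
    """
    if not pairs:
        raise InsufficientDataError("raw_score_kappa needs at least one pair")
    levels = sorted({p.total_a for p in pairs} | {p.total_b for p in pairs})
    if len(levels) == 1:
        raise UndefinedKappaError(
            "weighted kappa undefined: a single distinct total", perfect_agreement=True
        )
    pos = {v: i for i, v in enumerate(levels)}
    counts = np.zeros((len(levels), len(levels)), dtype=int)
    for p in pairs:
        counts[pos[p.total_a], pos[p.total_b]] += 1
    return _weighted_kappa(counts)


def agreement_report(pairs: list[PairedScores], cutoffs: CutoffSet | None = None) -> AgreementReport:
    """Assemble the full reproducibility report for a paired cohort."""
    if not pairs:
        raise InsufficientDataError("agreement_report needs at least one pair")
    percent_exact, hist, mean_abs = score_diff_summary(pairs)
    table = cross_classification(pairs, cutoffs)
    try:
        kappa: float | None = linear_weighted_kappa(table)
        defined = True
    except UndefinedKappaError:
        kappa, defined = None, False
    return AgreementReport(
        n_trials=len(pairs),
        n_exact=hist.get(0, 0),
        percent_exact=percent_exact,
        diff_histogram=hist,
        mean_abs_diff=mean_abs,
        cross_class=table,
        same_category_count=table.diagonal_count,
        weighted_kappa=kappa,
        kappa_defined=defined,
    )
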