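"""Paired-rater concordance statistics and linear weighted kappa."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from pharmcat import (
    CrossClassification,
    CutoffSet,
    InsufficientDataError,
    PairedScores,
    UndefinedKappaError,
    agreement_report,
    cross_classification,
    linear_weighted_kappa,
    pair_scores,
    raw_score_kappa,
    score_diff_summary,
    study_cutoffs,
)
from pharmcat.instrument import ScoreResult


def study_like_pairs():
    """60 pairs with the published discrepancy breakdown.

    46 identical, 11 differing by one point, 2 by two points and 1 by four
    points; every discrepant pair stays inside the medium category under
    the published cut-offs, so all 60 pairs share a category.
    """
    pairs = [PairedScores(f"S{i}", 22, 22) for i in range(46)]
    pairs += [PairedScores(f"D1_{i}", 22, 23) for i in range(11)]
    pairs += [PairedScores(f"D2_{i}", 21, 23) for i in range(2)]
    pairs += [PairedScores("D4_0", 21, 25)]
    return pairs


class TestScoreDiffSummary:
    def test_study_discrepancy_breakdown(self):
        percent_exact, hist, mean_abs = score_diff_summary(study_like_pairs())
        assert hist == {0: 46, 1: 11, 2: 2, 4: 1}
        assert mean_abs == 0.32          # 19 points over 60 trials
        assert percent_exact == 76.67    # displays as 77% at 0 decimals
        assert round(percent_exact) == 77

    def test_perfect_agreement(self):
        pairs = [PairedScores(f"T{i}", 20, 20) for i in range(5)]
        assert score_diff_summary(pairs) == (100.0, {0: 5}, 0.0)

    def test_empty_input(self):
        with pytest.raises(InsufficientDataError):
            score_diff_summary([])

    @given(st.lists(st.tuples(st.integers(15, 44), st.integers(15, 44)), min_size=1, max_size=60),
           st.randoms(use_true_random=False))
    def test_permutation_invariance_and_exactness_link(self, totals, rnd):
        pairs = [PairedScores(f"T{i}", a, b) for i, (a, b) in enumerate(totals)]
        shuffled = list(pairs)
        rnd.shuffle(shuffled)
        assert score_diff_summary(pairs) == score_diff_summary(shuffled)
        percent_exact, hist, mean_abs = score_diff_summary(pairs)
        assert hist.get(0, 0) == sum(1 for a, b in totals if a == b)
        assert (mean_abs == 0.0) == (percent_exact == 100.0)
        assert sum(hist.values()) == len(pairs)


class TestCrossClassification:
    def test_diagonal_pairs(self):
        pairs = [PairedScores("a", 15, 15), PairedScores("b", 20, 21), PairedScores("c", 26, 30)]
        table = cross_classification(pairs, CutoffSet(19, 25))
        assert table.counts == ((1, 0, 0), (0, 1, 0), (0, 0, 1))

    def test_boundary_straddle(self):
        table = cross_classification([PairedScores("x", 19, 20)], CutoffSet(19, 25))
        assert table.counts[0][1] == 1
        assert table.diagonal_count == 0

    def test_study_like_pairs_all_same_category(self):
        table = cross_classification(study_like_pairs(), study_cutoffs())
        assert table.n == 60
        assert table.diagonal_count == 60

    def test_one_straddling_pair_gives_one_off_diagonal(self):
        pairs = study_like_pairs()[:-1] + [PairedScores("straddle", 19, 20)]
        table = cross_classification(pairs, study_cutoffs())
        assert table.n - table.diagonal_count == 1

    def test_invalid_table_shapes_rejected(self):
        with pytest.raises(ValueError):
            CrossClassification(counts=((1, 2), (3, 4)), n=10)
        with pytest.raises(ValueError):
            CrossClassification.from_array([[1, 0, 0], [0, -1, 0], [0, 0, 1]])


class TestLinearWeightedKappa:
    def test_perfect_agreement(self):
        assert linear_weighted_kappa(np.diag([20, 20, 20])) == 1.0

    def test_chance_agreement_is_exactly_zero(self):
        # counts equal the product of their margins / n: independence
        table = np.array([[1, 2, 3], [2, 4, 6], [3, 6, 9]])
        assert linear_weighted_kappa(table) == 0.0

    def test_hand_derived_value(self):
        # n=80, margins (25,30,25) both sides; sum(w*p_obs) = 10/80,
        # sum(w*p_exp) = 2750/6400 -> kappa = 1 - 16/55 = 39/55
        table = np.array([[20, 5, 0], [5, 20, 5], [0, 5, 20]])
        assert linear_weighted_kappa(table) == pytest.approx(39 / 55, abs=1e-12)

    def test_single_cell_undefined_with_perfect_flag(self):
        with pytest.raises(UndefinedKappaError) as exc:
            linear_weighted_kappa(np.array([[0, 0, 0], [0, 7, 0], [0, 0, 0]]))
        assert exc.value.perfect_agreement

    def test_one_iff_diagonal(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            table = rng.integers(0, 10, (3, 3))
            if table.sum() == 0:
                continue
            rows = table.sum(axis=1)
            cols = table.sum(axis=0)
            if np.count_nonzero(rows) * np.count_nonzero(cols) <= 1:
                continue  # undefined denominator
            kappa = linear_weighted_kappa(table)
            if np.trace(table) == table.sum():
                assert kappa == 1.0
            else:
                assert kappa < 1.0

    def test_transpose_invariance(self):
        rng = np.random.default_rng(11)
        for _ in range(200):
            table = rng.integers(0, 15, (3, 3))
            if np.trace(table) == table.sum():
                continue
            assert linear_weighted_kappa(table) == pytest.approx(
                linear_weighted_kappa(table.T), abs=1e-12
            )

    def test_matches_sklearn_oracle_on_random_tables(self):
        """Independent textbook implementation over 1,000 random 3x3 tables."""
        from sklearn.metrics import cohen_kappa_score

        rng = np.random.default_rng(42)
        checked = 0
        while checked < 1000:
            table = rng.integers(0, 20, (3, 3))
            if table.sum() == 0 or np.trace(table) == table.sum():
                continue  # sklearn kappa undefined/degenerate cases aside
            y_a, y_b = [], []
            for i in range(3):
                for j in range(3):
                    y_a += [i] * table[i, j]
                    y_b += [j] * table[i, j]
            expected = cohen_kappa_score(y_a, y_b, weights="linear")
            assert linear_weighted_kappa(table) == pytest.approx(expected, abs=1e-12)
            checked += 1


class TestRawScoreKappa:
    def test_identical_pairs_multiple_totals(self):
        pairs = [PairedScores("a", 17, 17), PairedScores("b", 22, 22), PairedScores("c", 30, 30)]
        assert raw_score_kappa(pairs) == 1.0

    def test_single_total_undefined(self):
        with pytest.raises(UndefinedKappaError):
            raw_score_kappa([PairedScores("a", 20, 20)])


class TestAgreementReport:
    def test_study_like_configuration(self):
        report = agreement_report(study_like_pairs(), study_cutoffs())
        assert report.n_trials == 60
        assert report.n_exact == 46
        assert report.percent_exact == 76.67
        assert report.mean_abs_diff == 0.32
        assert report.same_category_count == 60

    def test_single_identical_pair(self):
        report = agreement_report([PairedScores("only", 22, 22)], study_cutoffs())
        assert report.n_trials == 1
        assert report.percent_exact == 100.0
        assert not report.kappa_defined  # one category only: kappa undefined

    def test_kappa_one_when_categories_vary_and_pairs_match(self):
        pairs = [PairedScores("a", 15, 15), PairedScores("b", 22, 22), PairedScores("c", 30, 30)]
        report = agreement_report(pairs, study_cutoffs())
        assert report.kappa_defined and report.weighted_kappa == 1.0

    def test_report_dict_is_json_friendly(self):
        import json

        doc = agreement_report(study_like_pairs(), study_cutoffs()).to_dict()
        json.dumps(doc)
        assert doc["percent_exact_0dp"] == 77.0
        assert doc["diff_histogram"] == {"0": 46, "1": 11, "2": 2, "4": 1}


class TestPairScores:
    def test_groups_two_raters_per_trial(self):
        scores = [
            ScoreResult("T1", "A", 20), ScoreResult("T1", "B", 21),
            ScoreResult("T2", "A", 26), ScoreResult("T2", "B", 26),
        ]
        pairs = pair_scores(scores)
        assert [(p.trial_id, p.total_a, p.total_b) for p in pairs] == [
            ("T1", 20, 21), ("T2", 26, 26)
        ]

    def test_rejects_unpaired_trial(self):
        with pytest.raises(ValueError, match="T1"):
            pair_scores([ScoreResult("T1", "A", 20)])
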