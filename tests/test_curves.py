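import numpy as np
import pytest
from scipy.integrate import quad
from sklearn.metrics import average_precision_score, roc_auc_score

from imbalmetrics import (
    LabeledScores,
    analytic_binormal_auc,
    cumulative_counts,
    mann_whitney_auc,
    partial_auc_from_curve,
    partial_roc_auc,
    pr_auc,
    pr_curve,
    roc_auc,
    roc_curve,
)

PERFECT = LabeledScores([1, 1, 0, 0], [0.9, 0.8, 0.2, 0.1])


class TestCumulativeCounts:
    def test_hand_enumeration(self, four_instance_data):
        assert cumulative_counts(four_instance_data) == [
            (4.0, 1, 0),
            (3.0, 1, 1),
            (2.0, 2, 1),
            (1.0, 2, 2),
        ]

    def test_tie_collapse(self):
        data = LabeledScores([1, 0, 1, 0], [0.5, 0.5, 0.5, 0.5])
        assert cumulative_counts(data) == [(0.5, 2, 2)]

    def test_duplicated_dataset_doubles_counts(self, four_instance_data):
        doubled = LabeledScores(
            np.tile(four_instance_data.labels, 2), np.tile(four_instance_data.scores, 2)
        )
        assert cumulative_counts(doubled) == [
            (t, 2 * tp, 2 * fp) for t, tp, fp in cumulative_counts(four_instance_data)
        ]


class TestCurves:
    def test_roc_enumeration(self, four_instance_data):
        assert roc_curve(four_instance_data).points == (
            (0.0, 0.0), (0.0, 0.5), (0.5, 0.5), (0.5, 1.0), (1.0, 1.0),
        )

    def test_roc_anchors_and_monotonicity(self, random_small_datasets):
        for data in random_small_datasets(50):
            curve = roc_curve(data)
            assert curve.points[0] == (0.0, 0.0) and curve.points[-1] == (1.0, 1.0)
            assert np.all(np.diff(curve.x) >= 0) and np.all(np.diff(curve.y) >= 0)

    def test_perfect_separation_passes_through_top_left(self):
        assert (0.0, 1.0) in roc_curve(PERFECT).points
        # precision is 1.0 at every recall over the positive-only prefix
        prefix = [p for r, p in pr_curve(PERFECT).points[:2]]
        assert prefix == [1.0, 1.0]
        assert (1.0, 1.0) in pr_curve(PERFECT).points

    def test_instance_order_invariance(self, four_instance_data):
        perm = np.array([2, 0, 3, 1])
        shuffled = LabeledScores(
            four_instance_data.labels[perm], four_instance_data.scores[perm]
        )
        assert roc_curve(shuffled).points == roc_curve(four_instance_data).points

    def test_pr_enumeration(self, four_instance_data):
        points = pr_curve(four_instance_data).points
        assert points == ((0.5, 1.0), (0.5, 0.5), (1.0, 2 / 3), (1.0, 0.5))

    def test_pr_all_tied_single_point_at_prevalence(self):
        data = LabeledScores([1, 0, 0, 0], [0.5, 0.5, 0.5, 0.5])
        assert pr_curve(data).points == ((1.0, 0.25),)


class TestAUC:
    def test_hand_examples(self, four_instance_data):
        assert roc_auc(four_instance_data).value == pytest.approx(0.75)
        assert pr_auc(four_instance_data).value == pytest.approx(5 / 6)
        assert roc_auc(PERFECT).value == 1.0
        assert pr_auc(PERFECT).value == 1.0

    def test_tied_pair_is_chance(self):
        data = LabeledScores([1, 0], [0.5, 0.5])
        assert roc_auc(data).value == 0.5

    def test_all_tied_pr_auc_equals_prevalence(self):
        data = LabeledScores([1, 0, 0, 0], [0.5] * 4)
        assert pr_auc(data).value == pytest.approx(0.25)

    def test_trapezoidal_equals_pair_counting(self, random_small_datasets):
        """Trapezoidal ROC-AUC is the tie-corrected Mann-Whitney statistic."""
        for data in random_small_datasets(300):
            assert roc_auc(data).value == pytest.approx(
                mann_whitney_auc(data), abs=1e-12
            )

    def test_agreement_with_sklearn(self, random_small_datasets):
        # independent reference implementation on tied, random data
        for data in random_small_datasets(100, max_size=200, seed=11):
            y, s = data.labels, data.scores
            assert roc_auc(data).value == pytest.approx(roc_auc_score(y, s), abs=1e-12)
            assert pr_auc(data).value == pytest.approx(
                average_precision_score(y, s), abs=1e-12
            )
            assert partial_roc_auc(data, 0.1).value == pytest.approx(
                roc_auc_score(y, s, max_fpr=0.1), abs=1e-12
            )


class TestPartialAUC:
    def test_chance_diagonal_maps_to_half(self):
        res = partial_auc_from_curve([0.0, 1.0], [0.0, 1.0], fpr_max=0.1)
        assert res.value == 0.5

    def test_perfect_classifier_maps_to_one(self):
        for fpr_max in (0.05, 0.1, 0.5, 1.0):
            assert partial_roc_auc(PERFECT, fpr_max).value == pytest.approx(1.0)

    def test_uncorrected_raw_area(self):
        res = partial_auc_from_curve([0.0, 1.0], [0.0, 1.0], 0.1, corrected=False)
        assert res.value == pytest.approx(0.1**2 / 2)

    def test_boundary_interpolation(self):
        # single step curve: TPR jumps to 1 at FPR 0.2; at fpr_max=0.1 the
        # diagonal segment contributes area 0.1*0.5/2 via interpolation
        res = partial_auc_from_curve([0.0, 0.2, 1.0], [0.0, 1.0, 1.0], 0.1, corrected=False)
        assert res.value == pytest.approx(0.1 * 0.5 / 2)

    def test_full_range_equals_roc_auc(self, four_instance_data):
        res = partial_roc_auc(four_instance_data, fpr_max=1.0, corrected=False)
        assert res.value == pytest.approx(roc_auc(four_instance_data).value)

    @pytest.mark.parametrize("fpr_max", [0.0, -0.1, 1.5])
    def test_fpr_max_domain(self, fpr_max, four_instance_data):
        with pytest.raises(ValueError):
            partial_roc_auc(four_instance_data, fpr_max)


class TestAnalyticOracles:
    @pytest.mark.parametrize("mu, expected", [(0.0, 0.5), (1.0, 0.7602), (1.5, 0.8556)])
    def test_binormal_closed_form(self, mu, expected):
        assert analytic_binormal_auc(mu) == pytest.approx(expected, abs=5e-5)

    def test_er_classifiers_by_numerical_integration(self):
        """Analytic ROC curves: good ER has TPR = FPR^(1/4), bad ER has
        TPR = 1-(1-FPR)^4; both integrate to 4/5 over the full range but
        differ sharply over FPR <= 0.1 after McClish standardization."""
        good = lambda x: x**0.25
        bad = lambda x: 1 - (1 - x) ** 4

        assert quad(good, 0, 1)[0] == pytest.approx(0.8, abs=1e-9)
        assert quad(bad, 0, 1)[0] == pytest.approx(0.8, abs=1e-9)

        def corrected(fn, fpr_max=0.1):
            raw = quad(fn, 0, fpr_max)[0]
            return 0.5 * (1 + (raw - fpr_max**2 / 2) / (fpr_max - fpr_max**2 / 2))

        assert corrected(good) == pytest.approx(0.7105, abs=5e-4)
        assert corrected(bad) == pytest.approx(0.5689, abs=5e-4)

        # the empirical estimator recovers the analytic values at large n
        grid = np.linspace(0, 0.1, 20_001)
        emp_good = partial_auc_from_curve(grid, good(grid), 0.1)
        emp_bad = partial_auc_from_curve(grid, bad(grid), 0.1)
        assert emp_good.value == pytest.approx(corrected(good), abs=1e-6)
        assert emp_bad.value == pytest.approx(corrected(bad), abs=1e-6)
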