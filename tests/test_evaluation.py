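import numpy as np
import pytest

from histoscore.errors import InvalidArgumentError
from histoscore.evaluation import (
    NO_OFF_DIAGONAL,
    accuracy,
    adjacent_confusion_mass,
    compare_to_expert,
    confusion_matrix,
    fit_saturation,
    saturation_exponential,
    saturation_michaelis,
)
from histoscore.schemes import ASHCROFT, INFLAMMATION

CLASSES = ASHCROFT.all_labels


class TestAccuracy:
    def test_identical_sequences(self):
        assert accuracy(["0", "1"], ["0", "1"]) == 1.0

    def test_partial_agreement(self):
        assert accuracy(["0", "1", "3", "5"], ["0", "1", "5", "5"]) == 0.75

    def test_length_mismatch(self):
        with pytest.raises(InvalidArgumentError):
            accuracy(["0"], ["0", "1"])

    def test_random_labels_hit_chance_level(self, rng):
        """Monte-Carlo null: accuracy of independent uniform labels over k
        classes is 1/k within 3 binomial sigma."""
        k, n = 5, 10_000
        ref = rng.integers(0, k, n)
        pred = rng.integers(0, k, n)
        acc = accuracy(ref.tolist(), pred.tolist())
        sigma = np.sqrt((1 / k) * (1 - 1 / k) / n)
        assert abs(acc - 1 / k) < 3 * sigma


class TestConfusionMatrix:
    def test_perfect_agreement_is_identity(self):
        labels = [c for c in CLASSES for _ in range(3)]
        cm = confusion_matrix(labels, labels, CLASSES)
        assert np.array_equal(cm.normalized, np.eye(len(CLASSES)))
        assert cm.zero_support == ()

    def test_hand_counted_row(self):
        ref = ["3"] * 5
        pred = ["3", "3", "3", "1", "5"]
        cm = confusion_matrix(ref, pred, CLASSES)
        row = cm.normalized[CLASSES.index("3")]
        assert row[CLASSES.index("3")] == pytest.approx(0.6)
        assert row[CLASSES.index("1")] == pytest.approx(0.2)
        assert row[CLASSES.index("5")] == pytest.approx(0.2)
        assert "0" in cm.zero_support  # unused reference classes flagged

    def test_rows_with_support_sum_to_one(self, rng):
        ref = rng.choice(CLASSES, 200).tolist()
        pred = rng.choice(CLASSES, 200).tolist()
        cm = confusion_matrix(ref, pred, CLASSES)
        support = cm.counts.sum(axis=1)
        for i, s in enumerate(support):
            if s > 0:
                assert cm.normalized[i].sum() == pytest.approx(1.0, abs=1e-9)
            else:
                assert cm.normalized[i].sum() == 0

    def test_accuracy_equals_support_weighted_diagonal(self, rng):
        """Algebraic identity: accuracy == sum_r (support_r/total) * M[r,r]."""
        ref = rng.choice(CLASSES, 300).tolist()
        pred = [r if rng.random() < 0.7 else rng.choice(CLASSES) for r in ref]
        cm = confusion_matrix(ref, pred, CLASSES)
        support = cm.counts.sum(axis=1)
        via_cm = float((support / support.sum()) @ np.diag(cm.normalized))
        assert accuracy(ref, pred) == pytest.approx(via_cm, abs=1e-12)

    def test_unknown_label_named_in_error(self):
        with pytest.raises(InvalidArgumentError, match="banana"):
            confusion_matrix(["banana"], ["0"], CLASSES)


class TestAdjacentConfusion:
    def test_no_misclassification_returns_sentinel(self):
        labels = [c for c in CLASSES for _ in range(2)]
        cm = confusion_matrix(labels, labels, CLASSES)
        assert adjacent_confusion_mass(cm, ASHCROFT) is NO_OFF_DIAGONAL

    def test_all_errors_adjacent_gives_one(self):
        ref = ["0", "1", "3", "5", "7"]
        pred = ["1", "0", "5", "3", "5"]
        cm = confusion_matrix(ref, pred, CLASSES)
        assert adjacent_confusion_mass(cm, ASHCROFT) == pytest.approx(1.0)

    def test_matches_direct_summation_on_random_matrices(self, rng):
        for _ in range(20):
            ref = rng.choice(ASHCROFT.class_labels, 150).tolist()
            pred = rng.choice(ASHCROFT.class_labels, 150).tolist()
            cm = confusion_matrix(ref, pred, CLASSES)
            got = adjacent_confusion_mass(cm, ASHCROFT)
            # direct summation oracle over the pair list
            order = {c: i for i, c in enumerate(ASHCROFT.class_labels)}
            mis = [(r, p) for r, p in zip(ref, pred) if r != p]
            if not mis:
                assert got is NO_OFF_DIAGONAL
            else:
                adj = sum(abs(order[r] - order[p]) == 1 for r, p in mis)
                assert got == pytest.approx(adj / len(mis), abs=1e-12)

    def test_ignore_column_is_excluded(self):
        ref = ["0", "0", "7"]
        pred = ["ignore", "1", "7"]  # one adjacent error, one into ignore
        cm = confusion_matrix(ref, pred, CLASSES)
        assert adjacent_confusion_mass(cm, ASHCROFT) == pytest.approx(1.0)

    def test_too_few_classes_rejected(self):
        from histoscore.schemes import ScoreScheme

        tiny = ScoreScheme("tiny", ("0", "1"), (0.0, 1.0))
        cm = confusion_matrix(["0", "1"], ["1", "0"], ("0", "1", "ignore"))
        with pytest.raises(InvalidArgumentError):
            adjacent_confusion_mass(cm, tiny)


class TestCompareToExpert:
    def test_exact_identity_line(self):
        x = np.linspace(0, 7, 20)
        fit = compare_to_expert(x, x, n_bootstrap=50, seed=0)
        assert fit.slope == pytest.approx(1.0)
        assert fit.intercept == pytest.approx(0.0, abs=1e-12)
        assert fit.r_squared == pytest.approx(1.0)

    def test_exact_affine_line(self):
        x = np.linspace(0, 5, 15)
        fit = compare_to_expert(2 * x + 1, x, n_bootstrap=50, seed=0)
        assert fit.slope == pytest.approx(2.0)
        assert fit.intercept == pytest.approx(1.0)

    def test_r_squared_is_symmetric(self, rng):
        x = rng.normal(size=40)
        y = 0.8 * x + rng.normal(scale=0.5, size=40)
        f_xy = compare_to_expert(y, x, n_bootstrap=10, seed=0)
        f_yx = compare_to_expert(x, y, n_bootstrap=10, seed=0)
        assert f_xy.r_squared == pytest.approx(f_yx.r_squared, abs=1e-12)

    def test_bootstrap_ci_covers_true_slope(self):
        """y = x + N(0, 0.3), n=72: the 5%/95% bootstrap CI should contain
        the true slope 1.0 in >= 9 of 10 replicate experiments."""
        hits = 0
        for rep in range(10):
            rng = np.random.default_rng(1000 + rep)
            x = rng.uniform(0, 7, 72)
            y = x + rng.normal(0, 0.3, 72)
            fit = compare_to_expert(y, x, n_bootstrap=500, seed=rep)
            if fit.ci_slope[0] <= 1.0 <= fit.ci_slope[1]:
                hits += 1
        assert hits >= 9

    def test_analytic_intervals_available(self, rng):
        x = rng.uniform(0, 7, 30)
        y = x + rng.normal(0, 0.2, 30)
        fit = compare_to_expert(y, x, ci_method="analytic")
        assert fit.ci_slope[0] < fit.slope < fit.ci_slope[1]

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(InvalidArgumentError):
            compare_to_expert([1, 2], [1, 2])
        with pytest.raises(InvalidArgumentError):
            compare_to_expert([1, 2, 3], [2, 2, 2])


class TestSaturationFit:
    @pytest.mark.parametrize(
        "form,fn,params",
        [
            ("michaelis", saturation_michaelis, (0.9, 40.0)),
            ("exponential", saturation_exponential, (0.85, 60.0)),
        ],
    )
    def test_noiseless_self_consistency(self, form, fn, params):
        """Fitting the asymptotic form to points generated from itself
        recovers the parameters within 1%."""
        n = np.array([25, 50, 100, 200, 400], dtype=float)
        a = fn(n, *params)
        got = fit_saturation(n, a, form)
        assert got[0] == pytest.approx(params[0], rel=0.01)
        assert got[1] == pytest.approx(params[1], rel=0.01)

    def test_unknown_form_rejected(self):
        with pytest.raises(InvalidArgumentError):
            fit_saturation([10, 20], [0.5, 0.6], "cubic")
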