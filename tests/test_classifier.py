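import numpy as np
import pytest

from histoscore.classifier import (
    CallableClassifier,
    TrainConfig,
    build_model,
    load_model,
    plateau_lr_trajectory,
    predict_proba,
    save_model,
    train,
)
from histoscore.dataset import load_labelled_folders, split_train_val
from histoscore.errors import (
    BackboneUnavailableError,
    InvalidArgumentError,
    ModelFormatError,
)
from histoscore.schemes import ASHCROFT, INFLAMMATION
from histoscore.smallcnn import SmallCNN


class TestBuildModel:
    def test_softmax_head_widths_per_scheme(self):
        fib = build_model("small_cnn", ASHCROFT.all_labels, seed=0)
        infl = build_model("small_cnn", INFLAMMATION.all_labels, seed=0)
        assert fib.n_classes == 6 and fib.net.head.W.shape[0] == 6
        assert infl.n_classes == 5 and infl.net.head.W.shape[0] == 5

    def test_same_seed_identical_initial_predictions(self, rng):
        tiles = [rng.integers(0, 256, (96, 96, 3), dtype=np.uint8) for _ in range(4)]
        a = build_model("small_cnn", ASHCROFT.all_labels, seed=3)
        b = build_model("small_cnn", ASHCROFT.all_labels, seed=3)
        assert np.array_equal(predict_proba(a, tiles), predict_proba(b, tiles))

    def test_transfer_backbone_unavailable_points_at_small_cnn(self):
        with pytest.raises(BackboneUnavailableError, match="small_cnn"):
            build_model("transfer_backbone", ASHCROFT.all_labels, seed=0)

    def test_probabilities_sum_to_one(self, rng):
        model = build_model("small_cnn", INFLAMMATION.all_labels, seed=1)
        tiles = [rng.integers(0, 256, (64, 64, 3), dtype=np.uint8) for _ in range(8)]
        probs = predict_proba(model, tiles)
        assert probs.shape == (8, 5)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)
        assert (probs >= 0).all()

    def test_duplicate_tiles_get_identical_vectors(self, rng):
        model = build_model("small_cnn", ASHCROFT.all_labels, seed=2)
        tile = rng.integers(0, 256, (64, 64, 3), dtype=np.uint8)
        probs = predict_proba(model, [tile, tile.copy()])
        assert np.array_equal(probs[0], probs[1])


class TestPlateauSchedule:
    def test_never_improving_sequence_matches_hand_simulation(self):
        """Factor 1/5, patience 3: reductions at epochs 5, 8, 11, then floor."""
        losses = [1.0, 0.9] + [0.9] * 13
        traj = plateau_lr_trajectory(losses, 5e-5, 0.2, 3, 1e-7)
        expected = (
            [5e-5] * 4 + [1e-5] * 3 + [2e-6] * 3 + [4e-7] * 3 + [1e-7] * 2
        )
        assert traj == pytest.approx(expected, rel=1e-12)

    def test_improvement_resets_the_counter(self):
        losses = [1.0, 0.95, 0.96, 0.97, 0.90, 0.91, 0.92, 0.93]
        traj = plateau_lr_trajectory(losses, 1e-3, 0.2, 3, 1e-7)
        assert traj == pytest.approx([1e-3] * 7 + [2e-4], rel=1e-12)

    def test_equal_loss_counts_as_no_improvement(self):
        traj = plateau_lr_trajectory([0.5, 0.5, 0.5, 0.5], 1e-2, 0.5, 3, 1e-7)
        assert traj == pytest.approx([1e-2, 1e-2, 1e-2, 5e-3])

    def test_floor_is_respected(self):
        traj = plateau_lr_trajectory([1.0] * 40, 1e-5, 0.1, 1, 1e-7)
        assert traj[0] == pytest.approx(1e-5)  # first loss always improves on inf
        assert traj[1] == pytest.approx(1e-6)
        assert min(traj) == pytest.approx(1e-7)
        assert all(a >= b for a, b in zip(traj, traj[1:]))  # non-increasing


class TestSmallCNNGradients:
    def test_backprop_matches_numeric_gradient(self):
        """Central-difference check on a handful of weights of a tiny net."""
        net = SmallCNN(3, input_px=8, channels=(4,), seed=0)
        rng = np.random.default_rng(1)
        x = rng.standard_normal((5, 3, 8, 8)).astype(np.float32)
        y = np.array([0, 1, 2, 1, 0])
        net.loss_and_grad(x, y)
        grads = [g.copy() for g in net.gradients()]
        params = net.parameters()
        eps = 1e-2
        probe = [(0, (0, 0)), (0, (3, 8)), (1, (2,)), (2, (1, 3)), (3, (0,))]
        for pi, idx in probe:
            orig = params[pi][idx]
            params[pi][idx] = orig + eps
            lp, _ = net.loss_and_grad(x, y)
            params[pi][idx] = orig - eps
            lm, _ = net.loss_and_grad(x, y)
            params[pi][idx] = orig
            numeric = (lp - lm) / (2 * eps)
            assert grads[pi][idx] == pytest.approx(numeric, rel=0.05, abs=1e-4)


class TestTraining:
    def test_zero_epochs_is_a_noop(self, fibrosis_tree, rng):
        ds = split_train_val(
            load_labelled_folders(fibrosis_tree[0], ASHCROFT.all_labels), 0.1, seed=0
        )
        model = build_model("small_cnn", ASHCROFT.all_labels, seed=0)
        before = [w.copy() for w in model.net.get_weights()]
        cfg = TrainConfig(max_epochs=0)
        model, curve = train(model, ds, cfg)
        assert len(curve) == 0
        for a, b in zip(before, model.net.get_weights()):
            assert np.array_equal(a, b)

    def test_learning_beats_chance_within_ten_epochs(self, fibrosis_tree):
        """Synthetic fibrosis data is separable: the small CNN must exceed
        the 1/6 chance level on validation within 10 epochs."""
        ds = split_train_val(
            load_labelled_folders(fibrosis_tree[0], ASHCROFT.all_labels), 0.1, seed=1
        )
        model = build_model("small_cnn", ASHCROFT.all_labels, seed=0, input_px=32)
        cfg = TrainConfig.desk_scale(max_epochs=10, seed=0)
        model, curve = train(model, ds, cfg)
        assert len(curve) <= 10
        assert max(curve.val_accuracy) > 1 / 6
        assert all(a >= b for a, b in zip(curve.lr, curve.lr[1:]))  # non-increasing
        assert curve.epochs == sorted(set(curve.epochs))

    def test_training_is_deterministic(self, fibrosis_tree):
        ds = split_train_val(
            load_labelled_folders(fibrosis_tree[0], ASHCROFT.all_labels), 0.1, seed=1
        )
        curves = []
        for _ in range(2):
            model = build_model("small_cnn", ASHCROFT.all_labels, seed=4, input_px=32)
            _, curve = train(model, ds, TrainConfig.desk_scale(max_epochs=2, seed=4))
            curves.append(curve.to_dataframe())
        assert curves[0].equals(curves[1])

    def test_config_validation(self):
        with pytest.raises(InvalidArgumentError):
            TrainConfig(plateau_factor=1.5)
        with pytest.raises(InvalidArgumentError):
            TrainConfig(initial_lr=1e-8, min_lr=1e-7)


class TestPersistence:
    def test_save_load_round_trip_preserves_predictions(self, tmp_path, rng):
        model = build_model("small_cnn", ASHCROFT.all_labels, seed=5,
                            scheme_name="ashcroft")
        tiles = [rng.integers(0, 256, (64, 64, 3), dtype=np.uint8) for _ in range(3)]
        before = predict_proba(model, tiles)
        save_model(model, tmp_path / "m.npz")
        loaded = load_model(tmp_path / "m.npz")
        assert loaded.class_names == model.class_names
        assert loaded.input_px == model.input_px
        assert loaded.scheme_name == "ashcroft"
        assert np.array_equal(predict_proba(loaded, tiles), before)

    def test_corrupt_archive_raises_clean_error(self, tmp_path):
        bad = tmp_path / "bad.npz"
        bad.write_bytes(b"garbage")
        with pytest.raises(ModelFormatError):
            load_model(bad)


def test_callable_classifier_satisfies_the_contract():
    clf = CallableClassifier(ASHCROFT.all_labels, lambda t: [1, 0, 0, 0, 0, 0])
    probs = clf.predict_proba([np.zeros((4, 4, 3))] * 3)
    assert probs.shape == (3, 6) and (probs[:, 0] == 1).all()
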