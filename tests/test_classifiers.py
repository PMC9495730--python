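"""Classifier-bank tests: building, training regimen, inference, persistence."""

import numpy as np
import pytest

from renalmil import classifiers, fixtures, tiling
from renalmil.classifiers import (
    PlateauScheduler,
    TrainingConfig,
    build_model,
    load_model,
    predict_batch,
    predict_patch,
    save_model,
    train,
)


def _patches_from_classes(class_names, scale=100, n_slides=2, seed=4):
    """Weakly-labeled patches from per-class synthetic slides."""
    spec = fixtures.default_spec(seed)
    cfg = tiling.TilingConfig(stride=100)
    patches, labels = [], []
    for cls in class_names:
        for rep in range(n_slides):
            img = fixtures.make_slide(spec, cls, seed=seed * 100 + rep + sum(map(ord, cls)))
            ps = tiling.extract_training_patches(img, f"{cls}_{rep}", cfg, scales=(scale,))
            patches += ps
            labels += [cls] * len(ps)
    return patches, labels


@pytest.fixture(scope="module")
def two_class_training():
    return _patches_from_classes(("ccRCC", "fat"))


@pytest.fixture(scope="module")
def trained_two_class(two_class_training):
    patches, labels = two_class_training
    model = build_model(100, 2, seed=1, class_order=("ccRCC", "fat"))
    model, history = train(model, patches, labels, TrainingConfig(seed=1))
    return model, history, patches


class TestBuildModel:
    def test_seeded_build_is_deterministic(self):
        a = build_model(100, 4, seed=1)
        b = build_model(100, 4, seed=1)
        for pa, pb in zip(a.network.parameters(), b.network.parameters()):
            np.testing.assert_array_equal(pa, pb)

    def test_output_layer_matches_class_count(self, rng):
        model = build_model(100, 4, seed=0)
        x = np.zeros((1, model.input_size, model.input_size, 3))
        probs = model.network.predict_proba(x)
        assert probs.shape == (1, 4)
        assert probs.sum() == pytest.approx(1.0, abs=1e-9)

    def test_input_size_scales_with_patch_scale(self):
        assert build_model(100, 4).input_size == 25
        assert build_model(200, 4).input_size == 25
        assert build_model(400, 4).input_size == 50

    def test_unsupported_architecture_rejected(self):
        with pytest.raises(ValueError):
            build_model(100, 4, architecture="resnet50")

    def test_scale_must_be_divisible_by_four(self):
        with pytest.raises(ValueError):
            build_model(101, 4)


class TestPlateauScheduler:
    def test_lr_decays_after_two_stale_epochs(self):
        # improvement in epoch 1, then stagnation: the learning rate holds
        # at 1e-3 until two epochs without improvement, then drops to 1e-4
        # epoch 1 sets the best; epochs 2-3 stagnate -> decay on the second
        # stale epoch; two more stale epochs -> decay again
        sched = PlateauScheduler(lr=1e-3, factor=0.1, plateau_patience=2, stop_patience=10)
        lrs = []
        for acc in [0.6, 0.6, 0.6, 0.6, 0.6]:
            lr, _ = sched.update(acc)
            lrs.append(lr)
        assert lrs == [1e-3, 1e-3, 1e-4, 1e-4, pytest.approx(1e-5)]

    def test_improvement_resets_counters(self):
        sched = PlateauScheduler(lr=1e-3, factor=0.1, plateau_patience=2, stop_patience=3)
        for acc in [0.5, 0.4, 0.6]:
            lr, stop = sched.update(acc)
        assert lr == 1e-3 and not stop

    def test_early_stop_after_patience(self):
        sched = PlateauScheduler(lr=1e-3, factor=0.1, plateau_patience=2, stop_patience=3)
        stops = [sched.update(0.5)[1] for _ in range(4)]
        assert stops == [False, False, False, True]


class TestTraining:
    def test_separable_two_class_fixture_reaches_high_validation_accuracy(
        self, trained_two_class
    ):
        _, history, _ = trained_two_class
        assert history[-1]["val_accuracy"] >= 0.95

    def test_history_records_loss_accuracy_and_lr(self, trained_two_class):
        _, history, _ = trained_two_class
        assert all({"epoch", "loss", "val_accuracy", "learning_rate"} <= set(h) for h in history)
        assert history[0]["learning_rate"] == 0.001

    def test_zero_epochs_returns_untrained_model(self, two_class_training):
        patches, labels = two_class_training
        model = build_model(100, 2, seed=2, class_order=("ccRCC", "fat"))
        before = [p.copy() for p in model.network.parameters()]
        model, history = train(model, patches, labels, TrainingConfig(seed=2, max_epochs=0))
        assert history == []
        for b, a in zip(before, model.network.parameters()):
            np.testing.assert_array_equal(b, a)

    def test_training_is_reproducible_bit_for_bit(self, two_class_training):
        patches, labels = two_class_training
        runs = []
        for _ in range(2):
            model = build_model(100, 2, seed=3, class_order=("ccRCC", "fat"))
            model, history = train(
                model, patches, labels, TrainingConfig(seed=3, max_epochs=3)
            )
            runs.append((model, history))
        assert runs[0][1] == runs[1][1]
        for a, b in zip(runs[0][0].network.state_arrays(), runs[1][0].network.state_arrays()):
            np.testing.assert_array_equal(a, b)

    def test_single_class_input_rejected(self, two_class_training):
        patches, labels = two_class_training
        model = build_model(100, 2, seed=1, class_order=("ccRCC", "fat"))
        with pytest.raises(ValueError):
            train(model, patches, ["ccRCC"] * len(patches), TrainingConfig(seed=1))

    def test_scale_mismatch_rejected(self, two_class_training):
        patches, labels = two_class_training
        model = build_model(200, 2, seed=1, class_order=("ccRCC", "fat"))
        with pytest.raises(ValueError):
            train(model, patches, labels, TrainingConfig(seed=1))


class TestInference:
    def test_prediction_is_deterministic(self, trained_two_class):
        model, _, patches = trained_two_class
        p1 = predict_patch(model, patches[0])
        p2 = predict_patch(model, patches[0])
        assert p1.label == p2.label
        np.testing.assert_array_equal(p1.probabilities, p2.probabilities)

    def test_probabilities_sum_to_one(self, trained_two_class):
        model, _, patches = trained_two_class
        preds = predict_batch(model, patches[:64])
        for p in preds:
            assert p.probabilities.sum() == pytest.approx(1.0, abs=1e-6)
            assert p.label == model.class_order[int(p.probabilities.argmax())]

    def test_holdout_patch_accuracy_on_separable_fixture(self, trained_two_class):
        model, _, _ = trained_two_class
        patches, labels = _patches_from_classes(("ccRCC", "fat"), n_slides=1, seed=9)
        preds = predict_batch(model, patches)
        acc = np.mean([p.label == l for p, l in zip(preds, labels)])
        assert acc >= 0.9

    def test_scale_mismatch_rejected(self, trained_two_class):
        model, _, _ = trained_two_class
        bad = tiling.Patch("s", 200, (0, 0), np.zeros((200, 200, 3), np.uint8))
        with pytest.raises(ValueError):
            predict_patch(model, bad)


class TestPersistence:
    def test_save_load_round_trip_identical_predictions(self, trained_two_class, tmp_path):
        model, _, patches = trained_two_class
        save_model(model, tmp_path / "m100")
        loaded = load_model(tmp_path / "m100")
        assert loaded.class_order == model.class_order
        assert loaded.scale == model.scale
        a = predict_batch(model, patches[:16])
        b = predict_batch(loaded, patches[:16])
        for pa, pb in zip(a, b):
            assert pa.label == pb.label
            np.testing.assert_array_equal(pa.probabilities, pb.probabilities)
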