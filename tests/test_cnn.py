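"""The patch CNN: architecture arithmetic, training contracts, inference."""

import numpy as np
import pytest

from hsipath.cnn import (
    ModelSpec,
    PatchClassifier,
    TrainConfig,
    build_model,
    predict_patches,
)
from hsipath.errors import ValidationError
from hsipath.evaluate import roc_auc
from hsipath.partition import balance_by_rotation

TINY = ModelSpec(input_side=21, input_bands=12, scale=0.0625)


def _rand_patches(n=4, side=21, bands=12, seed=0):
    return np.random.default_rng(seed).random((n, side, bands and side, bands)).astype(
        np.float32
    ).reshape(n, side, side, bands)


class TestArchitecture:
    def test_full_scale_shape_table(self):
        """The conv rows walk 87 -> 85 -> ... -> 73 with the published widths."""
        spec = ModelSpec()
        table = spec.shape_table()
        conv_rows = table[table.layer == "Conv2D"]["input"].tolist()
        assert conv_rows == [
            "87 x 87 x 275",
            "85 x 85 x 256",
            "83 x 83 x 256",
            "81 x 81 x 512",
            "79 x 79 x 512",
            "77 x 77 x 1024",
            "75 x 75 x 1024",
            "73 x 73 x 1024",
        ]
        assert table[table.layer == "Dense"]["input"].tolist() == ["1 x 1024", "1 x 256"]
        assert table[table.layer == "Softmax"]["input"].tolist() == ["1 x 2"]

    def test_first_conv_output_side_is_85(self):
        assert ModelSpec().spatial_sides()[1] == 85

    def test_spatial_recurrence_any_scale(self):
        sides = ModelSpec(scale=0.0625).spatial_sides()
        assert all(a - b == 2 for a, b in zip(sides, sides[1:]))
        assert sides == ModelSpec(scale=1.0).spatial_sides()

    def test_desk_scale_widths(self):
        assert ModelSpec(scale=0.0625).scaled_widths() == (16, 16, 32, 32, 64, 64, 64, 64)

    def test_rgb_variant_differs_only_in_bands(self):
        hsi = ModelSpec(input_bands=275)
        rgb = ModelSpec(input_bands=3)
        t_h = hsi.shape_table()
        t_r = rgb.shape_table()
        assert t_h.iloc[0]["input"] == "87 x 87 x 275"
        assert t_r.iloc[0]["input"] == "87 x 87 x 3"
        assert t_h.iloc[1:].equals(t_r.iloc[1:])

    def test_input_too_small_for_depth(self):
        with pytest.raises(ValidationError, match="too small"):
            ModelSpec(input_side=16)
        ModelSpec(input_side=17)  # the minimum that leaves a 1x1 pre-pool map

    def test_build_model_returns_table(self):
        model, table = build_model(TINY, seed=0)
        assert len(model.convs) == 8
        assert (table.layer == "Conv2D").sum() == 8


class TestInference:
    def test_probabilities_sum_to_one(self):
        model = PatchClassifier(TINY, seed=1)
        probs = model.predict_proba(_rand_patches(6))
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)
        assert probs.min() >= 0 and probs.max() <= 1

    def test_zeroed_logits_layer_gives_half(self):
        model = PatchClassifier(TINY, seed=1)
        model.dense2.w[...] = 0
        model.dense2.b[...] = 0
        probs = model.predict_proba(_rand_patches(3))
        np.testing.assert_array_equal(probs, 0.5)

    def test_duplicate_patches_score_identically(self):
        model = PatchClassifier(TINY, seed=2)
        x = _rand_patches(1)
        batch = np.concatenate([x, x])
        p = model.predict_proba(batch)
        np.testing.assert_array_equal(p[0], p[1])

    def test_band_mismatch_names_expected_and_got(self):
        model = PatchClassifier(TINY, seed=0)
        with pytest.raises(ValidationError, match="12.*7"):
            model.predict_proba(_rand_patches(2, bands=7))


class TestTraining:
    def test_same_seed_identical_first_epoch_loss(self, tiny_patches):
        train = tiny_patches.for_patients(["P1", "P2"])
        val = tiny_patches.for_patients(["P3"])
        spec = ModelSpec(input_side=train.side, input_bands=train.bands, scale=0.0625)
        losses = []
        for _ in range(2):
            model = PatchClassifier(spec, seed=5)
            res = model.fit(train, val, TrainConfig(epochs=1, batch_size=8, seed=5))
            losses.append(res.history.train_loss.iloc[0])
        assert losses[0] == losses[1]

    def test_learns_separable_synthetic_classes(self, tiny_trained):
        """Low-noise synthetic cohort: validation AUC >= 0.95 within 20 epochs."""
        assert tiny_trained.best_val_auc >= 0.95
        assert tiny_trained.config.epochs <= 20

    def test_shuffled_labels_give_chance_auc(self, tiny_patches):
        """Permutation null: with training AND validation labels scrambled,
        the validation AUC lands in the chance band."""
        rng = np.random.default_rng(3)
        train = tiny_patches.for_patients(["P1", "P2"])
        train.labels = rng.permutation(train.labels)
        # two held-out patients: enough patches for the null band to be stable
        val = tiny_patches.for_patients(["P3", "P4"])
        val.labels = rng.permutation(val.labels)
        spec = ModelSpec(input_side=train.side, input_bands=train.bands, scale=0.0625)
        model = PatchClassifier(spec, seed=3)
        model.fit(train, val, TrainConfig(epochs=2, batch_size=16, seed=3))
        auc = roc_auc(model.predict_tumor_probability(val), val.labels)
        assert 0.35 <= auc <= 0.65

    def test_patient_leakage_rejected(self, tiny_patches):
        train = tiny_patches.for_patients(["P1", "P2"])
        val = tiny_patches.for_patients(["P2"])
        model = PatchClassifier(
            ModelSpec(input_side=train.side, input_bands=train.bands, scale=0.0625)
        )
        with pytest.raises(ValidationError, match="leakage"):
            model.fit(train, val, TrainConfig(epochs=1))

    def test_single_class_training_rejected(self, tiny_patches):
        train = tiny_patches.for_patients(["P1"]).subset(
            tiny_patches.for_patients(["P1"]).labels == 1
        )
        val = tiny_patches.for_patients(["P4"])
        model = PatchClassifier(
            ModelSpec(input_side=train.side, input_bands=train.bands, scale=0.0625)
        )
        with pytest.raises(ValidationError, match="both classes"):
            model.fit(train, val, TrainConfig(epochs=1))

    def test_results_summary_and_prediction(self, tiny_trained, tiny_patches):
        text = tiny_trained.summary()
        assert "validation AUC" in text and "SGD" in text
        scores = predict_patches(tiny_trained, tiny_patches.for_patients(["P4"]))
        assert scores.min() >= 0 and scores.max() <= 1
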