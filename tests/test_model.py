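"""Multi-objective model: architecture, closed forms, gradients, training."""

import dataclasses
import math

import numpy as np
import pytest

from lungreport import (
    ActivationKind,
    GeneratorConfig,
    LocationLabel,
    MarginLabel,
    ModelConfig,
    SemanticLabels,
    TextureLabel,
    cross_entropy_loss,
    forward,
    init_model,
    predict,
    simulate_cohort,
    train,
)
from lungreport.evaluation import metrics_report
from lungreport.model import (
    PredictionResult,
    TowerConfig,
    _backward_tower,
    _forward_tower,
    _softmax,
    _Tower,
)


def _zero_weights(model):
    for tower in model.towers.values():
        for w in tower.weights:
            w[:] = 0.0
        for b in tower.biases:
            b[:] = 0.0


class TestArchitecture:
    def test_init_determinism(self, registry):
        cfg = ModelConfig(seed=0)
        a, b = init_model(cfg, registry), init_model(cfg, registry)
        for task in a.towers:
            for wa, wb in zip(a.towers[task].weights, b.towers[task].weights):
                assert np.array_equal(wa, wb)

    def test_tower_input_and_output_widths(self, registry):
        model = init_model(ModelConfig(), registry)
        assert model.towers["location"].weights[0].shape[1] == 113
        assert model.towers["margin"].weights[0].shape[1] == 107
        assert model.towers["texture"].weights[0].shape[1] == 107
        assert model.towers["location"].weights[2].shape[0] == 6
        assert model.towers["texture"].weights[2].shape[0] == 3
        assert model.towers["margin"].weights[2].shape[0] == 4

    def test_activation_assignment(self, registry):
        model = init_model(ModelConfig(), registry)
        assert model.towers["margin"].config.activation is ActivationKind.RELU
        assert model.towers["location"].config.activation is ActivationKind.TANH
        assert model.towers["texture"].config.activation is ActivationKind.TANH

    def test_dim_mismatch_rejected(self, registry):
        towers = ModelConfig().towers | {
            "location": TowerConfig(input_dims=107, n_classes=6)
        }
        with pytest.raises(ValueError, match="location"):
            init_model(ModelConfig(towers=towers), registry)


class TestForwardAndLoss:
    def test_zero_parameters_give_uniform_probabilities(self, registry, small_cohort):
        model = init_model(ModelConfig(standardize=False), registry)
        _zero_weights(model)
        result = forward(model, small_cohort.records[0])
        for task, k in (("location", 6), ("texture", 3), ("margin", 4)):
            assert result.probabilities[task] == pytest.approx(np.full(k, 1 / k))

    def test_softmax_closed_form(self):
        probs = _softmax(np.array([math.log(2), 0.0, 0.0]))
        assert probs == pytest.approx([0.5, 0.25, 0.25])

    def test_softmax_rows_sum_to_one_on_random_logits(self):
        rng = np.random.default_rng(0)
        z = rng.normal(0, 10, size=(50, 6))
        assert _softmax(z).sum(axis=1) == pytest.approx(np.ones(50), abs=1e-6)

    def test_inference_is_deterministic(self, registry, small_cohort):
        model = init_model(ModelConfig(standardize=False), registry)
        a = forward(model, small_cohort.records[0])
        b = forward(model, small_cohort.records[0])
        for task in a.probabilities:
            assert np.array_equal(a.probabilities[task], b.probabilities[task])

    def _prediction(self, p_loc, p_tex, p_mar):
        probs = {"location": np.asarray(p_loc), "texture": np.asarray(p_tex),
                 "margin": np.asarray(p_mar)}
        from lungreport.model import _argmax_labels
        return PredictionResult(probabilities=probs, labels=_argmax_labels(probs))

    def test_cross_entropy_closed_forms(self):
        gold = SemanticLabels(LocationLabel.RUL, TextureLabel.SOLID,
                              MarginLabel.SHARP_CIRCUMSCRIBED)
        # true-class probability 0.5 on texture, 1.0 elsewhere -> ln 2 total
        pred = self._prediction([1, 0, 0, 0, 0, 0], [0.5, 0.25, 0.25], [1, 0, 0, 0])
        assert cross_entropy_loss(pred, gold) == pytest.approx(math.log(2), abs=1e-5)
        # uniform 3-class prediction contributes ln 3
        pred = self._prediction([1, 0, 0, 0, 0, 0], [1 / 3] * 3, [1, 0, 0, 0])
        assert cross_entropy_loss(pred, gold) == pytest.approx(math.log(3), abs=1e-5)
        # perfect one-hot prediction: only the clipping floor remains
        pred = self._prediction([1, 0, 0, 0, 0, 0], [1, 0, 0], [1, 0, 0, 0])
        assert 0.0 <= cross_entropy_loss(pred, gold) <= 3 * 1.1e-7

    def test_argmax_tie_break_toward_first_class(self, registry, small_cohort):
        model = init_model(ModelConfig(standardize=False), registry)
        _zero_weights(model)
        model.mean = np.zeros(113)
        model.std = np.ones(113)
        labels = predict(model, small_cohort.records[0]).labels
        assert labels.location is LocationLabel.RUL
        assert labels.texture is TextureLabel.SOLID
        assert labels.margin is MarginLabel.SHARP_CIRCUMSCRIBED

    def test_texture_argmax(self):
        pred = self._prediction([1, 0, 0, 0, 0, 0], [0.1, 0.7, 0.2], [1, 0, 0, 0])
        assert pred.labels.texture is TextureLabel.SUBSOLID

    def test_untrained_model_cannot_predict(self, registry, small_cohort):
        model = init_model(ModelConfig(), registry)
        with pytest.raises(RuntimeError):
            predict(model, small_cohort.records[0])

    def test_non_finite_feature_raises(self, registry, small_cohort):
        model = init_model(ModelConfig(standardize=False), registry)
        bad = small_cohort.records[0]
        original = bad.features["original_glcm_Contrast"]
        bad.features["original_glcm_Contrast"] = float("nan")
        try:
            with pytest.raises(ValueError, match=bad.record_id):
                forward(model, bad)
        finally:
            bad.features["original_glcm_Contrast"] = original


def _tiny_tower(activation, seed=0):
    rng = np.random.default_rng(seed)
    tc = TowerConfig(input_dims=5, n_classes=3, hidden_widths=(4, 3),
                     dropout_rates=(0.0, 0.0), activation=activation)
    widths = (5, 4, 3, 3)
    weights = [rng.normal(0, 0.5, size=(widths[i + 1], widths[i]))
               for i in range(3)]
    biases = [rng.normal(0, 0.1, size=widths[i + 1]) for i in range(3)]
    return _Tower(config=tc, weights=weights, biases=biases)


def _batch_loss(tower, X, y):
    probs, _ = _forward_tower(tower, X, False, None)
    return float(-np.log(probs[np.arange(len(y)), y]).mean())


@pytest.mark.parametrize("activation", [ActivationKind.TANH, ActivationKind.RELU])
def test_gradient_check_against_finite_differences(activation):
    """Analytic backprop matches central finite differences on a tiny net."""
    rng = np.random.default_rng(3)
    tower = _tiny_tower(activation, seed=3)
    X = rng.normal(0, 1, size=(6, 5))
    y = rng.integers(0, 3, size=6)
    probs, cache = _forward_tower(tower, X, False, None)
    grads_w, grads_b = _backward_tower(tower, cache, probs, y)

    h = 1e-5
    for params, grads in ((tower.weights, grads_w), (tower.biases, grads_b)):
        for p, g in zip(params, grads):
            it = np.nditer(p, flags=["multi_index"])
            for _ in it:
                idx = it.multi_index
                keep = p[idx]
                p[idx] = keep + h
                up = _batch_loss(tower, X, y)
                p[idx] = keep - h
                down = _batch_loss(tower, X, y)
                p[idx] = keep
                numeric = (up - down) / (2 * h)
                denom = max(abs(numeric) + abs(g[idx]), 1e-8)
                assert abs(numeric - g[idx]) / denom < 1e-4


def test_inverted_dropout_expectation_matches_inference():
    """Mean of many training-mode passes approaches the inference activation."""
    rng = np.random.default_rng(0)
    tower = _tiny_tower(ActivationKind.TANH, seed=1)
    tower = _Tower(
        config=dataclasses.replace(tower.config, dropout_rates=(0.4, 0.0)),
        weights=tower.weights,
        biases=tower.biases,
    )
    X = rng.normal(0, 1, size=(1, 5))
    _, inference_cache = _forward_tower(tower, X, False, None)
    target = inference_cache["act"][0]

    draw_rng = np.random.default_rng(123)
    total = np.zeros_like(target)
    n = 20_000
    for _ in range(n):
        _, cache = _forward_tower(tower, X, True, draw_rng)
        total += cache["out"][0]
    mc_error = 3 * np.abs(target).max() / np.sqrt(n) * 2
    assert np.abs(total / n - target).max() < max(mc_error, 0.02)


class TestTraining:
    def test_loss_decreases_on_separable_cohort(self, registry, small_cohort):
        model = init_model(ModelConfig(epochs=10), registry)
        train(model, small_cohort)
        assert model.training_log[-1] < model.training_log[0]
        assert len(model.training_log) == 10

    def test_training_determinism(self, registry, small_cohort):
        runs = []
        for _ in range(2):
            model = init_model(ModelConfig(epochs=5, seed=2), registry)
            train(model, small_cohort)
            runs.append(model)
        for task in runs[0].towers:
            for wa, wb in zip(runs[0].towers[task].weights,
                              runs[1].towers[task].weights):
                assert np.array_equal(wa, wb)

    def test_overfit_capacity_on_highly_separable_cohort(self, registry):
        cohort = simulate_cohort(GeneratorConfig(n=200, seed=0, effect_size=5.0),
                                 registry)
        model = init_model(ModelConfig(seed=0), registry)  # default 50 epochs
        train(model, cohort)
        gold = [r.labels for r in cohort]
        predicted = [predict(model, r).labels for r in cohort]
        report = metrics_report(gold, predicted)
        for task in ("location", "texture", "margin"):
            assert report.macro_f1(task) == pytest.approx(1.0)

    def test_unlabeled_or_empty_cohort_rejected(self, registry, small_cohort):
        model = init_model(ModelConfig(), registry)
        stripped = small_cohort.subset(range(5))
        stripped.records[2] = type(stripped.records[2])(
            record_id="x", features=stripped.records[2].features,
            size_mm=5.0, labels=None)
        with pytest.raises(ValueError):
            train(model, stripped)
        with pytest.raises(ValueError):
            train(model, small_cohort.subset([]))
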