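"""AM-CNN architecture contracts, attention path, training behaviour."""

import numpy as np
import pytest

from mmbn import nn
from mmbn.amcnn import (
    AMCNN,
    ModelConfig,
    TrainConfig,
    attention_gates,
    build_model,
    predict,
    train,
)


@pytest.fixture()
def tiny_model():
    return build_model(
        ModelConfig(n_channels=6, n_branches=2, conv_kernels=4, fusion_kernels=(3, 2), seed=1)
    )


def separable_inputs(rng, n, N=6, branches=2, gap=3.0):
    """Linearly separable toy inputs: class shifts the mean of branch 0."""
    X = rng.normal(size=(n, N, N, branches)).astype(np.float32)
    y = rng.integers(0, 2, size=n)
    X[y == 1, :, :, 0] += gap
    return X, y


class TestArchitecture:
    def test_reference_shapes(self):
        """23-channel default build: 5290 flattened features, 384-deep
        concatenation, 8-unit attention bottleneck."""
        model = build_model(ModelConfig())
        shapes = model.layer_output_shapes()
        assert model.flatten_length == 5290
        assert shapes["L11"] == (5290,)
        assert model.concat_depth == 384
        assert shapes["L8"] == (23, 23, 384)
        assert shapes["L4"] == (8,)
        assert model.branches[0].fc1.W.value.shape == (16, 8)
        assert shapes["L9"] == (23, 23, 32)
        assert shapes["L10"] == (23, 23, 10)
        assert shapes["L12"] == (2,)

    def test_shape_arithmetic_n10(self):
        model = build_model(ModelConfig(n_channels=10))
        assert model.flatten_length == 10 * 10 * 10

    def test_runtime_shapes_match_declared(self, tiny_model, rng):
        x = rng.normal(size=(3, 6, 6, 2)).astype(np.float32)
        s1, s2, s7 = tiny_model.branches[0].forward(x[..., :1], train=False)
        declared = tiny_model.layer_output_shapes()
        assert s1.shape[1:] == declared["L1"]
        assert s2.shape[1:] == declared["L2"]
        assert s7.shape[1:] == declared["L7"]
        assert tiny_model.forward(x).shape == (3, 2)

    def test_input_shape_validated(self, tiny_model, rng):
        with pytest.raises(ValueError, match="expected input"):
            tiny_model.forward(rng.normal(size=(3, 6, 6, 5)).astype(np.float32))

    def test_invalid_config(self):
        with pytest.raises(ValueError):
            ModelConfig(conv_kernels=15, reduction_ratio=2)
        with pytest.raises(ValueError):
            ModelConfig(kernel_size=4)

    def test_attention_ablation_removes_only_l3_l6(self):
        """The comparison model drops the attention path; convolutional and
        batch-normalization parameters are untouched."""
        full = build_model(ModelConfig(seed=0))
        bare = build_model(ModelConfig(seed=0, attention=False))
        assert not hasattr(bare.branches[0], "fc1")
        n_att = 8 * (16 * 8 + 8 + 8 * 16 + 16)  # per-branch bottleneck params
        assert sum(p.value.size for p in full.params) - sum(
            p.value.size for p in bare.params
        ) == n_att
        shapes = bare.layer_output_shapes()
        assert "L4" not in shapes and shapes["L8"] == (23, 23, 384)


class TestAttention:
    def test_zero_maps_give_half_gates(self):
        """sigmoid(0) = 0.5: with zero inputs every map is scaled by 0.5."""
        W1 = np.zeros((4, 8))
        W2 = np.zeros((8, 4))
        gates = attention_gates(np.zeros((5, 5, 8)), W1, W2)
        assert np.allclose(gates, 0.5)

    def test_zero_weights_give_half_gates(self, rng):
        gates = attention_gates(rng.normal(size=(5, 5, 8)), np.zeros((4, 8)), np.zeros((8, 4)))
        assert np.allclose(gates, 0.5)

    def test_branch_matches_hand_rolled_oracle(self, tiny_model, rng):
        """The in-model attention path reproduces the explicit
        pool -> bottleneck -> sigmoid arithmetic."""
        br = tiny_model.branches[0]
        maps = rng.normal(size=(1, 6, 6, 4)).astype(np.float32)
        expected = attention_gates(
            maps[0],
            br.fc1.W.value.T,
            br.fc2.W.value.T,
            b1=br.fc1.b.value,
            b2=br.fc2.b.value,
        )
        got = br.sigmoid.forward(
            br.fc2.forward(br.relu3.forward(br.fc1.forward(br.gap.forward(maps))))
        )
        assert np.allclose(got[0], expected, atol=1e-6)

    def test_gates_in_unit_interval(self, tiny_model, rng):
        br = tiny_model.branches[0]
        maps = rng.normal(scale=5.0, size=(2, 6, 6, 4)).astype(np.float32)
        gates = br.sigmoid.forward(
            br.fc2.forward(br.relu3.forward(br.fc1.forward(br.gap.forward(maps))))
        )
        assert (gates > 0).all() and (gates < 1).all()


class TestBatchNorm:
    def test_training_mode_normalizes_batch(self, rng):
        """On a large batch the normalized output has per-channel mean ~ beta
        and sd ~ |gamma|."""
        bn = nn.BatchNorm(3)
        bn.gamma.value[...] = [2.0, 0.5, 1.0]
        bn.beta.value[...] = [1.0, -1.0, 0.0]
        x = rng.normal(loc=5.0, scale=3.0, size=(200, 4, 4, 3)).astype(np.float32)
        out = bn.forward(x, train=True)
        assert np.allclose(out.mean(axis=(0, 1, 2)), bn.beta.value, atol=1e-3)
        assert np.allclose(out.std(axis=(0, 1, 2)), np.abs(bn.gamma.value), atol=5e-3)

    def test_inference_uses_running_stats(self, rng):
        bn = nn.BatchNorm(2)
        x = rng.normal(size=(50, 3, 3, 2)).astype(np.float32)
        for _ in range(30):
            bn.forward(x, train=True)
        out = bn.forward(x, train=False)
        assert np.allclose(out.mean(axis=(0, 1, 2)), 0.0, atol=0.15)


class TestGradients:
    def test_directional_derivative(self, tiny_model, rng):
        """Backprop gradient agrees with a finite-difference directional
        derivative through the whole graph."""
        X = rng.normal(size=(4, 6, 6, 2)).astype(np.float32)
        y = np.array([0, 1, 1, 0])
        model = tiny_model
        for p in model.params:
            p.grad[...] = 0.0
        model.loss.forward(model.forward(X, train=True), y)
        model.backward(model.loss.backward())
        g = np.concatenate([p.grad.ravel() for p in model.params]).astype(np.float64)
        eps = 1e-2 / np.linalg.norm(g)
        w0 = model.get_weights()
        model.set_weights([w - eps * p.grad for w, p in zip(w0, model.params)])
        lm = model.loss.forward(model.forward(X, train=True), y)
        model.set_weights([w + eps * p.grad for w, p in zip(w0, model.params)])
        lp = model.loss.forward(model.forward(X, train=True), y)
        model.set_weights(w0)
        fd = (lp - lm) / (2 * eps)
        assert fd == pytest.approx(g @ g, rel=5e-3)


class TestTraining:
    def test_probabilities_valid_and_deterministic(self, tiny_model, rng):
        x = rng.normal(size=(5, 6, 6, 2)).astype(np.float32)
        p = tiny_model.predict_proba(x)
        assert p.shape == (5, 2)
        assert (p >= 0).all()
        assert np.allclose(p.sum(axis=1), 1.0, atol=1e-6)
        assert np.array_equal(p, tiny_model.predict_proba(x))
        single = predict(tiny_model, x[0])
        assert np.allclose(single, p[0])

    def test_zero_epochs_returns_untrained(self, tiny_model, rng):
        X, y = separable_inputs(rng, 12)
        w0 = tiny_model.get_weights()
        history = train(tiny_model, (X, y), TrainConfig(epochs=0, seed=0))
        assert history == []
        assert all(np.array_equal(a, b) for a, b in zip(w0, tiny_model.get_weights()))

    def test_single_class_rejected(self, tiny_model, rng):
        X = rng.normal(size=(8, 6, 6, 2)).astype(np.float32)
        with pytest.raises(ValueError, match="both classes"):
            train(tiny_model, (X, np.zeros(8, dtype=int)), TrainConfig(epochs=1))

    def test_overfits_separable_data(self, rng):
        """Sanity: an easily separable toy problem is learned to 100%
        training accuracy within a few epochs."""
        model = build_model(
            ModelConfig(n_channels=6, n_branches=2, conv_kernels=4, fusion_kernels=(3, 2), seed=2)
        )
        X, y = separable_inputs(rng, 40)
        history = train(
            model, (X, y), TrainConfig(epochs=25, batch_size=8, patience=None, seed=3)
        )
        acc = (model.predict_proba(X).argmax(axis=1) == y).mean()
        assert acc == 1.0
        assert len(history) == 25

    def test_shuffled_labels_stay_near_chance(self, rng):
        """Label-shuffled data carries no signal: held-out accuracy stays in
        a wide chance band."""
        model = build_model(
            ModelConfig(n_channels=6, n_branches=2, conv_kernels=4, fusion_kernels=(3, 2), seed=4)
        )
        X = rng.normal(size=(60, 6, 6, 2)).astype(np.float32)
        y = rng.permutation(np.repeat([0, 1], 30))
        train(model, (X[:40], y[:40]), TrainConfig(epochs=8, batch_size=8, patience=None, seed=5))
        acc = (model.predict_proba(X[40:]).argmax(axis=1) == y[40:]).mean()
        assert 0.2 <= acc <= 0.8

    def test_training_determinism(self, rng):
        X, y = separable_inputs(rng, 16)
        cfg = ModelConfig(n_channels=6, n_branches=2, conv_kernels=4, fusion_kernels=(3, 2), seed=6)
        runs = []
        for _ in range(2):
            m = build_model(cfg)
            train(m, (X, y), TrainConfig(epochs=3, batch_size=8, seed=9))
            runs.append(m.predict_proba(X))
        assert np.array_equal(runs[0], runs[1])
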