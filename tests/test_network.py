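"""Spearman layers, proportional thresholding and MMBN assembly."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from mmbn.io import WindowSample
from mmbn.network import (
    LayerNetwork,
    build_layer,
    build_mmbn,
    n_retained_edges,
    spearman_matrix,
    spearman_weight,
    threshold_layer,
)
from mmbn.synthetic import SyntheticConfig, generate_recording
from mmbn.wavelet import decompose_window


def rank_then_pearson(x, y):
    """Independent oracle: explicit average ranks, then product-moment."""
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    return np.corrcoef(rx, ry)[0, 1]


class TestSpearmanWeight:
    def test_identity_and_antitone(self):
        x = np.array([3.0, 1.0, 4.0, 1.5, 9.0])
        assert spearman_weight(x, x) == pytest.approx(1.0)
        assert spearman_weight(np.arange(6.0), np.arange(6.0)[::-1]) == pytest.approx(-1.0)

    def test_hand_case(self):
        """1 - 6*sum(d^2)/(L(L^2-1)) with d^2 summing to 4 over L=5: 0.8."""
        assert spearman_weight([1, 2, 3, 4, 5], [2, 1, 4, 3, 5]) == pytest.approx(0.8, abs=1e-15)

    def test_matches_tie_free_formula(self, rng):
        for _ in range(50):
            x, y = rng.normal(size=(2, 64))
            d = stats.rankdata(x) - stats.rankdata(y)
            expected = 1 - 6 * (d**2).sum() / (64 * (64**2 - 1))
            assert spearman_weight(x, y) == pytest.approx(expected, abs=1e-12)

    def test_ties_use_average_ranks(self, rng):
        x = rng.integers(0, 5, size=40).astype(float)  # heavy ties
        y = rng.integers(0, 5, size=40).astype(float)
        assert spearman_weight(x, y) == pytest.approx(
            stats.spearmanr(x, y).statistic, abs=1e-12
        )

    def test_constant_series_zero_with_warning(self):
        with pytest.warns(UserWarning, match="constant"):
            assert spearman_weight(np.ones(10), np.arange(10.0)) == 0.0

    def test_input_validation(self):
        with pytest.raises(ValueError):
            spearman_weight([1.0, 2.0], [3.0, 4.0])
        with pytest.raises(ValueError):
            spearman_weight([1.0, np.nan, 2.0], [1.0, 2.0, 3.0])

    def test_matrix_matches_pairwise(self, rng):
        series = rng.normal(size=(6, 100))
        w = spearman_matrix(series)
        for i in range(6):
            for j in range(i + 1, 6):
                assert w[i, j] == pytest.approx(
                    spearman_weight(series[i], series[j]), abs=1e-12
                )
        assert np.allclose(w, w.T) and not w.diagonal().any()

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_scale_invariance(self, seed):
        """Rank correlations ignore positive channel rescaling."""
        r = np.random.default_rng(seed)
        series = r.normal(size=(4, 50))
        scaled = series * r.uniform(0.1, 10.0, size=(4, 1))
        assert np.allclose(spearman_matrix(series), spearman_matrix(scaled), atol=1e-12)


@pytest.fixture()
def bandset(rng):
    return decompose_window(rng.normal(size=(23, 256)), fs=256.0)


class TestBuildLayer:
    def test_pair_count_and_bounds(self, bandset):
        layer = build_layer(bandset, 0)
        iu = np.triu_indices(23, 1)
        assert iu[0].size == 253
        vals = layer.weights[iu]
        assert ((vals >= -1) & (vals <= 1)).all()
        assert not layer.thresholded

    def test_identical_channels_weight_one(self, rng):
        x = rng.normal(size=256)
        bs = decompose_window(np.stack([x, x]), fs=256.0)
        assert build_layer(bs, 3).weights[0, 1] == pytest.approx(1.0)

    def test_permutation_equivariance(self, rng):
        data = rng.normal(size=(6, 256))
        perm = np.array([3, 1, 5, 0, 2, 4])
        w1 = build_layer(decompose_window(data, fs=256.0), 2).weights
        w2 = build_layer(decompose_window(data[perm], fs=256.0), 2).weights
        assert np.allclose(w2, w1[np.ix_(perm, perm)], atol=1e-12)

    def test_bad_band_index(self, bandset):
        with pytest.raises(IndexError):
            build_layer(bandset, 8)


class TestThreshold:
    def test_edge_count_n23(self, bandset):
        layer = threshold_layer(build_layer(bandset, 0), 0.30)
        assert n_retained_edges(23, 0.30) == 76
        assert layer.n_edges == 76
        assert np.allclose(layer.weights, layer.weights.T)

    def test_keep_all_is_identity(self, bandset):
        raw = build_layer(bandset, 1)
        kept = threshold_layer(raw, 1.0)
        assert np.allclose(kept.weights, raw.weights)

    def test_retains_largest_signed_weights(self, bandset):
        raw = build_layer(bandset, 0)
        kept = threshold_layer(raw, 0.30)
        iu = np.triu_indices(23, 1)
        retained = kept.weights[iu][kept.weights[iu] != 0]
        dropped_max = raw.weights[iu][kept.weights[iu] == 0].max()
        assert retained.min() >= dropped_max

    def test_magnitude_mode(self):
        w = np.array([[0, -0.9, 0.1], [-0.9, 0, 0.2], [0.1, 0.2, 0]], dtype=float)
        layer = LayerNetwork(weights=w, band_index=0)
        signed = threshold_layer(layer, 1 / 3)
        assert signed.weights[1, 2] == pytest.approx(0.2)  # most positive
        magn = threshold_layer(LayerNetwork(weights=w, band_index=0), 1 / 3, by_magnitude=True)
        assert magn.weights[0, 1] == pytest.approx(-0.9)  # largest |w|

    def test_tie_break_lexicographic(self):
        w = np.ones((4, 4)) - np.eye(4)
        kept = threshold_layer(LayerNetwork(weights=w, band_index=0), 0.5)
        iu = np.triu_indices(4, 1)
        # ceil(0.5 * 6) = 3 edges: the first three pairs in (i, j) order
        retained_pairs = [(i, j) for i, j in zip(*iu) if kept.weights[i, j] != 0]
        assert retained_pairs == [(0, 1), (0, 2), (0, 3)]

    def test_monotone_nesting(self, bandset):
        """Edges kept at fraction f1 <= f2 are a subset of those at f2."""
        raw = build_layer(bandset, 4)
        small = threshold_layer(raw, 0.1).weights != 0
        large = threshold_layer(raw, 0.4).weights != 0
        assert (small <= large).all()

    def test_invalid_fraction_and_rethreshold(self, bandset):
        raw = build_layer(bandset, 0)
        for f in (0.0, -0.2, 1.5):
            with pytest.raises(ValueError):
                threshold_layer(raw, f)
        with pytest.raises(ValueError, match="already"):
            threshold_layer(threshold_layer(raw, 0.3), 0.3)


class TestBuildMMBN:
    def test_shapes_and_determinism(self, rng):
        win = WindowSample(data=rng.normal(size=(23, 256)), label=1, start_time=0.0)
        net = build_mmbn(win)
        assert net.n_layers == 8 and net.n_nodes == 23
        assert net.as_array().shape == (8, 23, 23)
        assert net.label == 1
        assert all(layer.n_edges == 76 for layer in net.layers)
        net2 = build_mmbn(win)
        assert np.array_equal(net.as_array(), net2.as_array())

    def test_driven_band_has_strongest_layer(self):
        """Coupling only in band 0 concentrates retained weight in layer 0."""
        cfg = SyntheticConfig(
            n_channels=10, duration=1.0, noise_sd=0.1, seed=9,
            band_coupling_seizure=(0.95,) + (0.0,) * 7,
        )
        rec = generate_recording("seizure", cfg)
        win = WindowSample(data=rec.signal[:, :256], label=1, start_time=0.0)
        net = build_mmbn(win)
        means = [layer.weights[np.triu_indices(10, 1)].mean() for layer in net.layers]
        assert np.argmax(means) == 0
        assert means[0] > 2 * max(means[1:])
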