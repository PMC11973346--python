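"""Sensor-graph construction: PLI, distance adjacency, normalization, GCN."""

import numpy as np
import pytest

from glcnet.core_data import ConfigurationError, EpochSet, ValidationError
from glcnet.graph import (
    AdjacencySpec,
    GCNLayerParams,
    compute_distance_adjacency,
    compute_pli_adjacency,
    gcn_layer_forward,
    normalize_adjacency,
)
from conftest import random_adjacency


def _epochs_from_channels(chans, sfreq=250.0):
    data = np.stack(chans)[None, :, :]
    return EpochSet(data=data, labels=np.zeros(1, dtype=int), sfreq=sfreq)


class TestPLI:
    def test_identical_channels_score_zero(self):
        """Zero-lag coupling is invisible to the phase lag index."""
        rng = np.random.default_rng(0)
        x = rng.standard_normal(1000)
        e = _epochs_from_channels([x, x.copy()])
        adj = compute_pli_adjacency(e, band_hz=(8.0, 12.0))
        assert adj.matrix[0, 1] <= 1e-9

    def test_quarter_cycle_lag_scores_near_one(self):
        """sin vs cos at 10 Hz: constant 90-degree lag, PLI >= 0.99."""
        t = np.arange(1000) / 250.0
        x = np.sin(2 * np.pi * 10 * t)
        y = np.cos(2 * np.pi * 10 * t)
        e = _epochs_from_channels([x, y])
        adj = compute_pli_adjacency(e, band_hz=(8.0, 12.0))
        assert adj.matrix[0, 1] >= 0.99

    def test_independent_noise_below_monte_carlo_null(self):
        """60 s of independent noise: PLI under the null's 95th percentile."""
        rng = np.random.default_rng(7)
        n = 60 * 250
        e = _epochs_from_channels([rng.standard_normal(n),
                                   rng.standard_normal(n)])
        adj = compute_pli_adjacency(e, band_hz=(8.0, 12.0))
        # null: |mean of random signs| over the effective sample count;
        # band-limiting leaves roughly bandwidth*duration independent phases
        eff = int(4.0 * 60)  # 4 Hz band x 60 s
        null_rng = np.random.default_rng(123)
        null = np.abs(null_rng.choice([-1.0, 1.0], size=(2000, eff)).mean(axis=1))
        assert adj.matrix[0, 1] <= np.quantile(null, 0.95)
        assert adj.matrix[0, 1] <= 0.1

    def test_constant_channel_rejected_by_name(self):
        x = np.random.default_rng(1).standard_normal(500)
        e = _epochs_from_channels([x, np.zeros(500)])
        with pytest.raises(ValidationError, match="channel 1"):
            compute_pli_adjacency(e, band_hz=(8.0, 12.0))

    def test_matrix_invariants(self, tiny_epochs):
        adj = compute_pli_adjacency(tiny_epochs, band_hz=(8.0, 12.0))
        m = adj.matrix
        assert np.allclose(m, m.T)
        assert np.all(np.diag(m) == 0)
        assert m.min() >= 0 and m.max() <= 1


class TestDistanceAdjacency:
    def test_collinear_min_max_normalization(self):
        """3 equally spaced sensors: neighbors 1.0, far pair 0.0 (brute force)."""
        pos = np.array([[0.0, 0, 0], [1.0, 0, 0], [2.0, 0, 0]])
        a = compute_distance_adjacency(pos).matrix
        assert a[0, 1] == pytest.approx(1.0)
        assert a[1, 2] == pytest.approx(1.0)
        assert a[0, 2] == pytest.approx(0.0)

    def test_symmetric_zero_diagonal(self):
        rng = np.random.default_rng(2)
        a = compute_distance_adjacency(rng.standard_normal((6, 3))).matrix
        assert np.allclose(a, a.T)
        assert np.all(np.diag(a) == 0)

    def test_two_sensors_degenerate_minmax(self):
        """Single pair: min == max defines d = 0, hence A = 1."""
        a = compute_distance_adjacency(np.array([[0.0, 0, 0], [1.0, 0, 0]])).matrix
        assert a[0, 1] == pytest.approx(1.0)

    def test_missing_positions(self):
        with pytest.raises(ConfigurationError):
            compute_distance_adjacency(None)

    def test_duplicate_positions(self):
        with pytest.raises(ConfigurationError, match="duplicate"):
            compute_distance_adjacency(np.zeros((3, 3)))


class TestNormalizeAdjacency:
    def test_edgeless_graph_gives_identity(self):
        adj = AdjacencySpec(mode="custom", matrix=np.zeros((4, 4)))
        np.testing.assert_allclose(normalize_adjacency(adj).matrix, np.eye(4))

    def test_path_graph_hand_computed(self):
        """3-node path: diag (1/2, 1/3, 1/2), edges 1/sqrt(6)."""
        a = np.array([[0.0, 1, 0], [1, 0, 1], [0, 1, 0]])
        s = normalize_adjacency(AdjacencySpec(mode="custom", matrix=a)).matrix
        expected = np.array([
            [1 / 2, 1 / np.sqrt(6), 0],
            [1 / np.sqrt(6), 1 / 3, 1 / np.sqrt(6)],
            [0, 1 / np.sqrt(6), 1 / 2],
        ])
        np.testing.assert_allclose(s, expected, atol=1e-12)

    @pytest.mark.parametrize("seed", range(10))
    def test_spectral_radius_bounded(self, seed):
        """Eigenvalue oracle over random symmetric non-negative matrices."""
        rng = np.random.default_rng(seed)
        for _ in range(10):
            n = rng.integers(2, 12)
            adj = random_adjacency(int(n), seed=int(rng.integers(1 << 30)))
            s = normalize_adjacency(adj).matrix
            eig = np.linalg.eigvalsh(s)
            assert np.abs(eig).max() <= 1 + 1e-6
            assert np.allclose(s, s.T)

    def test_asymmetric_rejected(self):
        m = np.array([[0.0, 1], [0, 0]])
        with pytest.raises(ValidationError):
            AdjacencySpec(mode="custom", matrix=m)


class TestGCNLayer:
    def test_identity_prop_reduces_to_linear_map(self):
        rng = np.random.default_rng(3)
        h = rng.standard_normal((5, 4))
        w = rng.standard_normal((4, 2))
        prop = normalize_adjacency(AdjacencySpec(mode="custom", matrix=np.zeros((5, 5))))
        params = GCNLayerParams(weight=w, bias=np.zeros(2), activation="identity")
        np.testing.assert_allclose(gcn_layer_forward(h, prop, params), h @ w)

    def test_complete_graph_identical_rows(self):
        n = 4
        a = np.ones((n, n)) - np.eye(n)
        prop = normalize_adjacency(AdjacencySpec(mode="custom", matrix=a))
        h = np.tile(np.array([1.0, -2.0, 0.5]), (n, 1))
        params = GCNLayerParams(weight=np.eye(3), bias=np.zeros(3),
                                activation="identity")
        out = gcn_layer_forward(h, prop, params)
        assert np.allclose(out, out[0])

    def test_matches_triple_loop_oracle(self):
        """sigma(S H W + b) vs an explicit scalar triple loop."""
        rng = np.random.default_rng(11)
        n, fi, fo = 4, 3, 2
        adj = random_adjacency(n, seed=5)
        prop = normalize_adjacency(adj)
        h = rng.standard_normal((n, fi))
        w = rng.standard_normal((fi, fo))
        b = rng.standard_normal(fo)
        params = GCNLayerParams(weight=w, bias=b, activation="relu")
        out = gcn_layer_forward(h, prop, params)
        s = prop.matrix
        oracle = np.zeros((n, fo))
        for i in range(n):
            for o in range(fo):
                acc = b[o]
                for j in range(n):
                    for k in range(fi):
                        acc += s[i, j] * h[j, k] * w[k, o]
                oracle[i, o] = max(acc, 0.0)
        np.testing.assert_allclose(out, oracle, atol=1e-6)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(13)
        n, fi, fo = 6, 4, 3
        adj = random_adjacency(n, seed=21)
        h = rng.standard_normal((n, fi))
        params = GCNLayerParams(weight=rng.standard_normal((fi, fo)),
                                bias=rng.standard_normal(fo))
        perm = rng.permutation(n)
        out = gcn_layer_forward(h, normalize_adjacency(adj), params)
        adj_p = AdjacencySpec(mode="custom", matrix=adj.matrix[np.ix_(perm, perm)])
        out_p = gcn_layer_forward(h[perm], normalize_adjacency(adj_p), params)
        np.testing.assert_allclose(out_p, out[perm], atol=1e-10)

    def test_shape_mismatch_reported(self):
        prop = normalize_adjacency(random_adjacency(4))
        params = GCNLayerParams(weight=np.zeros((3, 2)), bias=np.zeros(2))
        with pytest.raises(ValidationError, match="feature dim"):
            gcn_layer_forward(np.zeros((4, 5)), prop, params)
        with pytest.raises(ValidationError, match="channels"):
            gcn_layer_forward(np.zeros((5, 3)), prop, params)
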