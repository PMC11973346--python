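"""Architecture assembly: layer parameter counts, LSTM recursion, forward
contracts, ablation, gradients through the full network, checkpoints."""

import numpy as np
import pytest

from glcnet.core_data import ConfigurationError
from glcnet.graph import AdjacencySpec
from glcnet.losses_metrics import batch_loss, batch_loss_grad
from glcnet.model import (
    LSTMParams,
    ModelConfig,
    ablate,
    build_glcnet,
    count_parameters,
    load_checkpoint,
    lstm_forward,
    save_checkpoint,
)
from conftest import random_adjacency


@pytest.fixture(scope="module")
def published_model():
    """204 gradiometers; T chosen so the graph-layer node dim is 240."""
    cfg = ModelConfig(n_channels=204, n_times=2400, n_classes=4,
                      avg_window=480,
                      adjacency=AdjacencySpec(mode="custom",
                                              matrix=np.zeros((204, 204))))
    return build_glcnet(cfg, seed=0)


class TestParameterCounts:
    """Trainable-scalar counts of the published layer stack."""

    def test_first_graph_layer(self, published_model):
        layer = published_model.submodules["gcn_branch"].layers[0]
        assert layer.n_params() == 15_424  # 240*64 + 64

    def test_second_graph_layer(self, published_model):
        layer = published_model.submodules["gcn_branch"].layers[1]
        assert layer.n_params() == 325  # 64*5 + 5

    def test_channel_aggregating_conv(self, published_model):
        layer = published_model.submodules["gcn_branch"].layers[2]
        assert layer.n_params() == 529_056  # 288*9*204 + 288

    def test_grouped_spatial_conv(self, published_model):
        layer = published_model.submodules["spatial_branch"].layers[0]
        assert layer.n_params() == 59_040  # 288*204 + 288

    def test_batchnorm_sizes(self, published_model):
        assert published_model.submodules["frontend"].layers[2].n_params() == 18
        assert published_model.submodules["gcn_branch"].layers[4].n_params() == 576
        assert published_model.submodules["spatial_branch"].layers[2].n_params() == 576

    def test_classifier(self, published_model):
        assert published_model.submodules["classifier"].n_params() == 5_764  # 1440*4+4

    def test_classifier_input_width(self, published_model):
        assert published_model.submodules["classifier"].linear.weight.data.shape[0] == 1440

    def test_total_is_sum_of_submodules(self, published_model):
        reg = published_model.parameter_registry()
        assert count_parameters(published_model, "all") == sum(reg.values())

    def test_unknown_submodule_lists_names(self, published_model):
        with pytest.raises(KeyError, match="gcn_branch"):
            count_parameters(published_model, "bogus")


class TestLSTMForward:
    def _params(self, d, h, seed=0, zero=False):
        rng = np.random.default_rng(seed)
        mk = (lambda *s: np.zeros(s)) if zero else (lambda *s: rng.standard_normal(s) * 0.5)
        return LSTMParams(
            w_i=mk(d, h), w_f=mk(d, h), w_o=mk(d, h), w_c=mk(d, h),
            u_i=mk(h, h), u_f=mk(h, h), u_o=mk(h, h), u_c=mk(h, h),
            b_i=mk(h)[0] if zero else mk(h), b_f=mk(h)[0] if zero else mk(h),
            b_o=mk(h)[0] if zero else mk(h), b_c=mk(h)[0] if zero else mk(h),
        ) if not zero else LSTMParams(
            w_i=np.zeros((d, h)), w_f=np.zeros((d, h)), w_o=np.zeros((d, h)),
            w_c=np.zeros((d, h)), u_i=np.zeros((h, h)), u_f=np.zeros((h, h)),
            u_o=np.zeros((h, h)), u_c=np.zeros((h, h)), b_i=np.zeros(h),
            b_f=np.zeros(h), b_o=np.zeros(h), b_c=np.zeros(h))

    def test_zero_weights_give_zero_hidden(self):
        params = self._params(2, 3, zero=True)
        out = lstm_forward(params, np.ones((4, 2)))
        np.testing.assert_array_equal(out, np.zeros((4, 3)))

    def test_matches_scalar_loop_oracle(self):
        """Gate equations transcribed one scalar at a time."""
        d, h, steps = 2, 2, 3
        params = self._params(d, h, seed=5)
        rng = np.random.default_rng(6)
        seq = rng.standard_normal((steps, d))

        def sig(v):
            return 1 / (1 + np.exp(-v))

        hprev = np.zeros(h)
        cprev = np.zeros(h)
        expected = []
        for t in range(steps):
            row = np.zeros(h)
            cnew = np.zeros(h)
            for j in range(h):
                zi = params.b_i[j]; zf = params.b_f[j]
                zo = params.b_o[j]; zc = params.b_c[j]
                for k in range(d):
                    zi += params.w_i[k, j] * seq[t, k]
                    zf += params.w_f[k, j] * seq[t, k]
                    zo += params.w_o[k, j] * seq[t, k]
                    zc += params.w_c[k, j] * seq[t, k]
                for k in range(h):
                    zi += params.u_i[k, j] * hprev[k]
                    zf += params.u_f[k, j] * hprev[k]
                    zo += params.u_o[k, j] * hprev[k]
                    zc += params.u_c[k, j] * hprev[k]
                i_g, f_g, o_g = sig(zi), sig(zf), sig(zo)
                cnew[j] = f_g * cprev[j] + i_g * np.tanh(zc)
                row[j] = o_g * np.tanh(cnew[j])
            hprev, cprev = row, cnew
            expected.append(row)
        np.testing.assert_allclose(lstm_forward(params, seq),
                                   np.array(expected), atol=1e-6)

    def test_hidden_states_bounded(self):
        params = self._params(3, 4, seed=9)
        out = lstm_forward(params, np.random.default_rng(2).standard_normal((20, 3)) * 10)
        assert np.all(np.abs(out) < 1.0)

    def test_layer_form_agrees_with_functional_form(self):
        from glcnet.nnops import LSTM

        rng = np.random.default_rng(31)
        layer = LSTM(3, 4, rng)
        params = LSTMParams(
            w_i=layer.w["i"].data, w_f=layer.w["f"].data,
            w_o=layer.w["o"].data, w_c=layer.w["c"].data,
            u_i=layer.u["i"].data, u_f=layer.u["f"].data,
            u_o=layer.u["o"].data, u_c=layer.u["c"].data,
            b_i=layer.b["i"].data, b_f=layer.b["f"].data,
            b_o=layer.b["o"].data, b_c=layer.b["c"].data)
        seq = rng.standard_normal((6, 3))
        np.testing.assert_allclose(layer.forward(seq[None])[0],
                                   lstm_forward(params, seq), atol=1e-12)


class TestForward:
    def _bands(self, cfg, n=4, seed=0):
        rng = np.random.default_rng(seed)
        return rng.standard_normal((n, cfg.n_bands, cfg.n_channels, cfg.n_times))

    def test_rows_are_log_probabilities(self, tiny_model, tiny_model_config):
        logp = tiny_model.forward(self._bands(tiny_model_config), mode="eval")
        np.testing.assert_allclose(np.exp(logp).sum(axis=1), 1.0, atol=1e-5)

    def test_eval_mode_deterministic(self, tiny_model, tiny_model_config):
        x = self._bands(tiny_model_config)
        a = tiny_model.forward(x, mode="eval")
        b = tiny_model.forward(x, mode="eval")
        np.testing.assert_array_equal(a, b)

    def test_batch_equals_concatenated_singles(self, tiny_model, tiny_model_config):
        x = self._bands(tiny_model_config, n=5)
        batch = tiny_model.forward(x, mode="eval")
        singles = np.concatenate([tiny_model.forward(x[i:i + 1], mode="eval")
                                  for i in range(5)])
        np.testing.assert_allclose(batch, singles, atol=1e-5)

    def test_shape_mismatch_rejected(self, tiny_model):
        with pytest.raises(Exception, match="band tensor"):
            tiny_model.forward(np.zeros((2, 9, 5, 40)))

    def test_train_mode_reproducible_for_same_seed(self, tiny_model_config):
        x = self._bands(tiny_model_config)
        outs = []
        for _ in range(2):
            m = build_glcnet(tiny_model_config, seed=7)
            outs.append(m.forward(x, mode="train"))
        np.testing.assert_array_equal(outs[0], outs[1])


class TestGradientThroughNetwork:
    def test_backprop_matches_finite_differences(self, tiny_model, tiny_model_config):
        """Loss gradient vs central differences on 10 random weights."""
        x = self._bands = np.random.default_rng(1).standard_normal(
            (3, tiny_model_config.n_bands, tiny_model_config.n_channels,
             tiny_model_config.n_times))
        y = np.array([0, 1, 2])
        m = tiny_model
        # deterministic path for finite differences: disable dropout
        for mod in m.submodules.values():
            for l in getattr(mod, "layers", []):
                if hasattr(l, "p") and hasattr(l, "rng"):
                    l.p = 0.0

        def loss():
            return batch_loss(m.forward(x, mode="train"), y, "ece")

        for p in m.parameters():
            p.grad[...] = 0.0
        logp = m.forward(x, mode="train")
        m.backward(batch_loss_grad(logp, y, "ece"))
        rng = np.random.default_rng(5)
        params = m.parameters()
        for _ in range(10):
            p = params[rng.integers(len(params))]
            idx = tuple(rng.integers(s) for s in p.data.shape)
            eps = 1e-5
            p.data[idx] += eps
            fp = loss()
            p.data[idx] -= 2 * eps
            fm = loss()
            p.data[idx] += eps
            num = (fp - fm) / (2 * eps)
            denom = max(abs(num), abs(p.grad[idx]), 1e-4)
            assert abs(p.grad[idx] - num) / denom < 1e-3, p.name


class TestAblation:
    def test_removed_branch_absent_from_registry(self, tiny_model_config):
        cfg = ablate(tiny_model_config, "module1_gcn")
        m = build_glcnet(cfg, seed=0)
        reg = m.parameter_registry()
        assert "gcn_branch" not in reg and "frontend" not in reg

    def test_ablated_forward_still_normalized(self, tiny_model_config):
        rng = np.random.default_rng(0)
        x = rng.standard_normal((3, tiny_model_config.n_bands,
                                 tiny_model_config.n_channels,
                                 tiny_model_config.n_times))
        for removed in ("module1_gcn", "module2_spatialconv", "module3_lstm"):
            m = build_glcnet(ablate(tiny_model_config, removed), seed=0)
            logp = m.forward(x, mode="eval")
            np.testing.assert_allclose(np.exp(logp).sum(axis=1), 1.0, atol=1e-5)

    def test_parameter_totals(self, tiny_model_config):
        full = count_parameters(build_glcnet(tiny_model_config, seed=0))
        for removed in ("module1_gcn", "module3_lstm"):
            abl = count_parameters(build_glcnet(ablate(tiny_model_config, removed), seed=0))
            assert abl < full
        # the spatial conv stays (it feeds the LSTM); only the fusion changes
        abl2 = count_parameters(
            build_glcnet(ablate(tiny_model_config, "module2_spatialconv"), seed=0))
        assert abl2 <= full

    def test_double_ablation_rejected(self, tiny_model_config):
        cfg = ablate(tiny_model_config, "module1_gcn")
        with pytest.raises(ConfigurationError, match="one module"):
            ablate(cfg, "module3_lstm")

    def test_unknown_module_rejected(self, tiny_model_config):
        with pytest.raises(ConfigurationError):
            ablate(tiny_model_config, "module4")


class TestConfigValidation:
    def test_divisibility_enforced(self):
        with pytest.raises(ConfigurationError, match="pool_factor"):
            ModelConfig(n_channels=4, n_times=45, adjacency=random_adjacency(4))

    def test_adjacency_channel_mismatch(self):
        cfg = ModelConfig(n_channels=8, n_times=40, avg_window=8,
                          adjacency=random_adjacency(4))
        with pytest.raises(ConfigurationError, match="channels"):
            build_glcnet(cfg)


def test_checkpoint_roundtrip(tmp_path, tiny_model, tiny_model_config):
    x = np.random.default_rng(8).standard_normal(
        (2, tiny_model_config.n_bands, tiny_model_config.n_channels,
         tiny_model_config.n_times))
    ref = tiny_model.forward(x, mode="eval")
    path = save_checkpoint(tiny_model, tmp_path / "ckpt.h5")
    restored = load_checkpoint(path)
    np.testing.assert_array_equal(restored.forward(x, mode="eval"), ref)
    assert restored.seed == tiny_model.seed
    assert restored.parameter_registry() == tiny_model.parameter_registry()
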