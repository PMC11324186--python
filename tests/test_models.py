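"""Tests for the encoding-model backbones: forward contracts, causality,
parameter budgets, prefilter integration, and checkpointing."""

import numpy as np
import pytest

from adaptrans import (AdapTransParams, Cochleagram, TeacherSpec,
                       apply_adaptrans, make_random_binary, make_step,
                       rectify)
from adaptrans._autodiff import Tensor
from adaptrans.models import (AdapTransLayer, CNNConfig, ModelConfig,
                              build_model, count_parameters, load_checkpoint,
                              prefilter_channels, save_checkpoint)

BF8 = np.geomspace(500.0, 22627.0, 8)


def _cfg(backbone, prefilter="adaptrans", **kw):
    base = dict(backbone=backbone, prefilter=prefilter, F=8, T=5, H=4,
                dt=0.005, band_freqs=BF8, smooth_len=20)
    base.update(kw)
    return ModelConfig(**base)


def _stim(T=120):
    return make_step(8, T, T // 6, 2 * T // 3, band_freqs=BF8)


ALL_BACKBONE_CONFIGS = [
    _cfg("L"), _cfg("LN"), _cfg("NRF"), _cfg("DNet"),
    CNNConfig(prefilter="adaptrans", F=3, T=4, n_bands_in=8, dt=0.005,
              band_freqs=BF8, cnn_channels=3, cnn_fc=7),
]


class TestForwardContracts:
    @pytest.mark.parametrize("config", ALL_BACKBONE_CONFIGS,
                             ids=lambda c: c.backbone)
    def test_output_length_equals_input_length(self, config):
        model = build_model(config, rng=0)
        for T in (60, 121):
            out = model.predict(_stim(T))
            assert out.shape == (T,)

    @pytest.mark.parametrize("config", ALL_BACKBONE_CONFIGS,
                             ids=lambda c: c.backbone)
    def test_causality(self, config):
        # perturbing the stimulus from bin t0 on leaves earlier output alone
        model = build_model(config, rng=1)
        stim = _stim(120)
        y1 = model.predict(stim)
        v2 = stim.values.copy()
        v2[:, 70:] += 3.0
        y2 = model.predict(Cochleagram(values=v2, band_freqs=BF8, dt=0.005))
        np.testing.assert_allclose(y1[:70], y2[:70], atol=1e-12)

    @pytest.mark.parametrize("config", ALL_BACKBONE_CONFIGS,
                             ids=lambda c: c.backbone)
    def test_instantiated_parameter_count_matches_budget(self, config):
        model = build_model(config, rng=0)
        assert model.n_parameters() == count_parameters(config)


class TestLinearModel:
    def test_zero_weights_constant_output(self):
        model = build_model(_cfg("L", prefilter="none"), rng=0)
        model.weights.data[:] = 0.0
        model.bias.data[:] = 1.7
        np.testing.assert_allclose(model.predict(_stim()), 1.7, atol=1e-14)

    def test_identity_tap_reproduces_band(self):
        model = build_model(_cfg("L", prefilter="none"), rng=0)
        strf = np.zeros_like(model.strf)
        strf[0, 0, 3, 0] = 1.0  # weight 1 at band 3, lag 0
        model.set_strf(strf)
        model.bias.data[:] = 0.0
        stim = make_random_binary(8, 100, rng=2, band_freqs=BF8)
        np.testing.assert_allclose(model.predict(stim), stim.values[3],
                                   atol=1e-14)

    def test_superposition_with_zero_bias(self):
        model = build_model(_cfg("L", prefilter="none"), rng=3)
        model.bias.data[:] = 0.0
        s1 = make_random_binary(8, 90, rng=0, band_freqs=BF8)
        s2 = make_random_binary(8, 90, rng=1, band_freqs=BF8)
        mix = Cochleagram(values=2.0 * s1.values + 0.5 * s2.values,
                          band_freqs=BF8, dt=0.005)
        np.testing.assert_allclose(
            model.predict(mix),
            2.0 * model.predict(s1) + 0.5 * model.predict(s2), atol=1e-10)

    def test_reproduces_teacher_exactly(self):
        # an L model whose prefilter equals the teacher's and whose STRF holds
        # the teacher readout at lag 0 reproduces the teacher PSTH exactly
        params = AdapTransParams.from_frequencies(BF8, dt=0.005)
        rng = np.random.default_rng(5)
        weights = rng.uniform(0.1, 1.0, (2, 8))
        teacher = TeacherSpec(params=params, weights=weights, bias=0.3,
                              sigma=0.0, n_repeats=1)
        config = _cfg("L", T=1)
        model = build_model(config, rng=0)
        strf = np.zeros_like(model.strf)
        strf[0, :, :, 0] = weights
        model.set_strf(strf)
        model.bias.data[:] = 0.3
        stim = make_random_binary(8, 300, rng=7, band_freqs=BF8)
        np.testing.assert_allclose(model.predict(stim), teacher.psth(stim),
                                   atol=1e-10)


class TestLNModel:
    def test_output_bounded_and_centered(self):
        model = build_model(_cfg("LN", prefilter="none"), rng=0)
        out = model.predict(_stim())
        assert np.all((out > 0) & (out < 1))

    def test_sigmoid_at_zero_preactivation(self):
        model = build_model(_cfg("LN", prefilter="none", use_batchnorm=False),
                            rng=0)
        model.weights.data[:] = 0.0
        model.bias.data[:] = 0.0
        np.testing.assert_allclose(model.predict(_stim()), 0.5, atol=1e-14)

    def test_monotone_in_preactivation(self):
        model = build_model(_cfg("LN", prefilter="none", use_batchnorm=False),
                            rng=0)
        model.weights.data[:] = 0.0
        outs = []
        for b in (-1.0, 0.0, 2.0):
            model.bias.data[:] = b
            outs.append(model.predict(_stim())[0])
        assert outs[0] < outs[1] < outs[2]


class TestNRF:
    def test_single_hidden_unit_reduces_to_ln_without_output_squash(self):
        config = _cfg("NRF", prefilter="none", H=1)
        model = build_model(config, rng=0)
        model.readout.data[:] = 1.0
        model.out_bias.data[:] = 0.0
        model.bn.gamma.data[:] = 1.0
        model.bn.beta.data[:] = 0.0
        ln = build_model(_cfg("LN", prefilter="none"), rng=0)
        ln.weights.data = model.weights.data.copy()
        ln.bias.data = model.hidden_bias.data.copy()
        stim = _stim()
        np.testing.assert_allclose(model.predict(stim), ln.predict(stim),
                                   atol=1e-10)


class TestDNet:
    def test_smoothing_preserves_dc(self):
        from adaptrans.models import _exp_smooth

        x = Tensor(np.zeros((2, 200)))
        x.data[:, 50] = 1.0
        d = Tensor(np.array([0.0, 3.0]))
        out = _exp_smooth(x, d, 60)
        np.testing.assert_allclose(out.data.sum(axis=1), 1.0, atol=1e-6)

    def test_d_zero_is_fastest_dynamic(self):
        from adaptrans.models import _exp_smooth

        x = Tensor(np.zeros((2, 100)))
        x.data[:, 10] = 1.0
        out = _exp_smooth(x, Tensor(np.array([0.0, 4.0])), 40).data
        # tau = 1 concentrates mass at the impulse; tau = 17 spreads it
        assert out[0, 10] > 0.6
        assert out[1, 10] < 0.1

    def test_taus_at_least_one(self):
        model = build_model(_cfg("DNet"), rng=0)
        model.d_hidden.data[:] = 0.0
        assert np.all(model.hidden_taus >= 1.0)


class TestCNN:
    def test_leaky_relu_slope(self):
        from adaptrans._autodiff import leaky_relu

        out = leaky_relu(Tensor(np.array([-10.0, 10.0])), 0.1)
        np.testing.assert_allclose(out.data, [-1.0, 10.0])

    def test_frequency_shrink_guard(self):
        with pytest.raises(ValueError):
            CNNConfig(prefilter="none", F=4, T=3, n_bands_in=8, dt=0.005,
                      band_freqs=BF8).n_freq_out


class TestPrefilterIntegration:
    @pytest.mark.parametrize("mode, channels", [("none", 1),
                                                ("ic_adaptation", 1),
                                                ("adaptrans", 2),
                                                ("adaptrans_plus_raw", 3)])
    def test_channel_counts(self, mode, channels):
        assert prefilter_channels(mode) == channels
        model = build_model(_cfg("L", prefilter=mode), rng=0)
        x = model.input_channels(_stim())
        assert x.shape[0] == channels

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            prefilter_channels("bogus")

    def test_adaptrans_doubles_input_weights(self):
        n_none = count_parameters(_cfg("L", prefilter="none"))
        n_adap = count_parameters(_cfg("L", prefilter="adaptrans"))
        assert n_adap == 2 * (n_none - 1) + 1 + 3 * 8

    def test_none_mode_independent_of_filter_parameters(self):
        model = build_model(_cfg("L", prefilter="none"), rng=0)
        assert model.prefilter_layer is None

    def test_layer_matches_reference_filtering(self):
        # the differentiable filtering agrees with the numpy reference path
        layer = AdapTransLayer(BF8, dt=0.005)
        stim = make_random_binary(8, 200, rng=3, band_freqs=BF8)
        out = layer.forward(Tensor(stim.values)).data
        ref = apply_adaptrans(stim, layer.current_params, K=layer.K)
        np.testing.assert_allclose(out, ref.values, atol=1e-8)

    def test_rectified_channels_nonnegative(self):
        model = build_model(_cfg("L", prefilter="adaptrans"), rng=0)
        x = model.input_channels(_stim())
        assert np.all(x.data >= 0)


class TestPopulation:
    def test_n_one_matches_single_unit_shapes(self):
        model = build_model(_cfg("NRF", n_outputs=1), rng=0)
        assert model.predict(_stim()).shape == (120,)

    def test_multi_output_heads(self):
        model = build_model(_cfg("NRF", n_outputs=5), rng=0)
        out = model.predict(_stim())
        assert out.shape == (5, 120)

    def test_per_head_gradient_isolation(self):
        # zeroing one unit's target changes only shared-trunk gradients and
        # that head's readout row
        model = build_model(_cfg("NRF", n_outputs=3), rng=0)
        stim = _stim()
        target = np.ones((3, 120))

        def grads(tgt):
            for p in model.parameters():
                p.grad = None
            pred = model.forward(stim, training=False)
            diff = pred - Tensor(tgt)
            (diff * diff).mean().backward()
            return model.readout.grad.copy()

        g_base = grads(target)
        t2 = target.copy()
        t2[1] = 0.0
        g_mod = grads(t2)
        assert not np.allclose(g_base[1], g_mod[1])
        np.testing.assert_allclose(g_base[0], g_mod[0], atol=1e-12)
        np.testing.assert_allclose(g_base[2], g_mod[2], atol=1e-12)

    def test_invalid_output_count(self):
        with pytest.raises(ValueError):
            _cfg("NRF", n_outputs=0)


class TestConstraints:
    def test_parameters_stay_in_range_under_updates(self):
        from adaptrans._autodiff import AdamW

        layer = AdapTransLayer(BF8, dt=0.005)
        opt = AdamW(layer.parameters(), lr=0.5)
        stim = make_random_binary(8, 100, rng=0, band_freqs=BF8)
        for _ in range(20):
            opt.zero_grad()
            out = layer.forward(Tensor(stim.values))
            (out * out).mean().backward()
            opt.step()
            p = layer.current_params
            assert np.all((p.w >= 0) & (p.w <= 1))
            assert np.all((p.a_on > 0) & (p.a_on < 1))
            assert np.all((p.a_off > 0) & (p.a_off < 1))

    def test_w_initialized_at_075(self):
        layer = AdapTransLayer(BF8, dt=0.005)
        np.testing.assert_allclose(layer.current_params.w, 0.75, atol=1e-12)


class TestCheckpoint:
    @pytest.mark.parametrize("config", ALL_BACKBONE_CONFIGS[:4],
                             ids=lambda c: c.backbone)
    def test_round_trip(self, config, tmp_path):
        model = build_model(config, rng=0)
        stim = _stim()
        expected = model.predict(stim)
        path = tmp_path / "ckpt.npz"
        save_checkpoint(model, path)
        back = load_checkpoint(path)
        np.testing.assert_allclose(back.predict(stim), expected, atol=1e-12)
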