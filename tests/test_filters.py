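"""Unit and property tests for the paired ON/OFF filter module."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from adaptrans import (AdapTransParams, Cochleagram, a_from_tau,
                       apply_adaptrans, bode_curves, build_kernels,
                       ic_adaptation, init_time_constants, kernel_length,
                       make_step, offset_amplitude_closed_form, rectify,
                       tau_from_a, transfer_function)


class TestTimeConstantRule:
    @pytest.mark.parametrize("f_hz, dt, expected_steps", [
        (1000.0, 0.005, 37.0),    # 185 ms at 5 ms bins
        (10.0, 0.001, 395.0),     # 395 ms at 1 ms bins
        (1e6, 0.001, 1.0),        # rule goes negative -> clamped to 1 step
    ])
    def test_known_values(self, f_hz, dt, expected_steps):
        assert init_time_constants([f_hz], dt)[0] == pytest.approx(expected_steps)

    def test_monotone_non_increasing_in_frequency(self):
        freqs = np.geomspace(100.0, 40000.0, 50)
        tau = init_time_constants(freqs, 0.001)
        assert np.all(np.diff(tau) <= 1e-12)

    @pytest.mark.parametrize("freqs, dt", [([0.0], 0.005), ([-5.0], 0.005),
                                           ([1000.0], 0.0), ([1000.0], -1.0)])
    def test_invalid_arguments(self, freqs, dt):
        with pytest.raises(ValueError):
            init_time_constants(freqs, dt)


class TestDecayFactor:
    def test_tau_one(self):
        assert a_from_tau(1.0) == pytest.approx(np.exp(-1), abs=1e-12)

    def test_limit_toward_one(self):
        assert a_from_tau(1e9) == pytest.approx(1.0, abs=1e-8)

    def test_round_trip_at_reference_point(self):
        # a = 0.6 corresponds to tau ~ 1.958 steps
        assert tau_from_a(0.6) == pytest.approx(1.9576, abs=1e-4)
        assert a_from_tau(tau_from_a(0.6)) == pytest.approx(0.6, abs=1e-12)

    def test_strictly_increasing_in_tau(self):
        taus = np.linspace(1, 200, 100)
        assert np.all(np.diff(a_from_tau(taus)) > 0)

    def test_tau_below_one_rejected(self):
        with pytest.raises(ValueError):
            a_from_tau(0.5)


class TestKernelLength:
    def test_formula(self):
        p = AdapTransParams(w=[0.5], a_on=[a_from_tau(100.0)],
                            a_off=[a_from_tau(2.0)], dt=0.001,
                            band_freqs=[1000.0])
        assert kernel_length(p) == 301

    def test_minimal(self):
        p = AdapTransParams(w=[0.5], a_on=[a_from_tau(1.0)],
                            a_off=[a_from_tau(1.0)], dt=0.001,
                            band_freqs=[1000.0])
        assert kernel_length(p) == 4

    def test_truncation_captures_95_percent(self):
        # tail mass of the infinite exponential retained at K = 3 tau + 1
        for tau in [1, 2, 5, 17, 100, 1000]:
            a = a_from_tau(tau)
            K = 3 * tau + 1
            assert 1 - a ** K >= 1 - np.exp(-3)


class TestBuildKernels:
    def test_identity_when_w_zero(self):
        pair = build_kernels(0.0, 0.6, 0.6, 30)
        expected = np.zeros(30)
        expected[0] = 1.0
        np.testing.assert_allclose(pair.h_on, expected, atol=1e-15)

    def test_reference_values_untruncated_limit(self):
        # w=0.5, a=0.6: h_on = [1, -0.2, -0.12, -0.072, ...] with C = 1-a
        pair = build_kernels(0.5, 0.6, 0.6, 200)
        np.testing.assert_allclose(pair.h_on[:4], [1.0, -0.2, -0.12, -0.072],
                                   atol=1e-10)
        assert pair.c_on == pytest.approx(0.4, abs=1e-10)

    @given(w=st.floats(0.0, 1.0), a=st.floats(0.01, 0.99),
           K=st.integers(2, 300))
    @settings(deadline=None, max_examples=60)
    def test_sums_and_endpoints(self, w, a, K):
        pair = build_kernels(w, a, a, K)
        assert pair.h_on[0] == 1.0
        assert pair.h_off[0] == -w
        assert pair.h_on.sum() == pytest.approx(1 - w, abs=1e-10)
        assert pair.h_off.sum() == pytest.approx(1 - w, abs=1e-10)

    def test_fully_transient_kernels_are_opposite(self):
        pair = build_kernels(1.0, 0.8, 0.8, 50)
        np.testing.assert_allclose(pair.h_off, -pair.h_on, atol=1e-14)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            build_kernels(0.5, 0.6, 0.6, 1)


class TestStepResponse:
    def test_zero_input_gives_zero_output(self, params, band_freqs):
        stim = Cochleagram(values=np.zeros((8, 100)), band_freqs=band_freqs,
                           dt=0.005)
        out = apply_adaptrans(stim, params)
        assert np.all(out.values == 0)

    @pytest.mark.parametrize("w", [0.0, 0.25, 0.75, 1.0])
    @pytest.mark.parametrize("a", [0.5, 0.9])
    def test_onset_offset_and_sustained_levels(self, w, a):
        p = AdapTransParams(w=[w], a_on=[a], a_off=[a], dt=0.005,
                            band_freqs=[1000.0])
        K = 60  # plateau longer than the kernel: levels are exact
        stim = make_step(1, 300, 80, 220, dt=0.005, band_freqs=[1000.0])
        out = apply_adaptrans(stim, p, K=K)
        on, off = out.on[0], out.off[0]
        assert on[80] == pytest.approx(1.0, abs=1e-10)
        assert off[80] == pytest.approx(-w, abs=1e-10)
        assert on[219] == pytest.approx(1 - w, abs=1e-10)
        assert off[219] == pytest.approx(1 - w, abs=1e-10)
        assert on[220] == pytest.approx(-w, abs=1e-10)
        assert off[220] == pytest.approx(1.0, abs=1e-10)

    def test_polarity_symmetry_of_event_amplitudes(self):
        # with a_on = a_off, onsets on the ON channel and offsets on the OFF
        # channel have the same amplitude, and vice versa
        p = AdapTransParams(w=[0.65], a_on=[0.85], a_off=[0.85], dt=0.005,
                            band_freqs=[1000.0])
        up = make_step(1, 250, 100, 250, dt=0.005, band_freqs=[1000.0])
        down = Cochleagram(values=1.0 - up.values, band_freqs=[1000.0],
                           dt=0.005)
        out_up = apply_adaptrans(up, p, K=80)
        out_down = apply_adaptrans(down, p, K=80)
        assert out_up.on[0, 100] == pytest.approx(out_down.off[0, 100], abs=1e-10)
        assert out_up.off[0, 100] == pytest.approx(out_down.on[0, 100], abs=1e-10)

    def test_fully_transient_responses_are_opposite(self):
        # w = 1 makes the kernels exact opposites, so the ON response to any
        # stimulus equals the OFF response to its complement, sample for sample
        p = AdapTransParams(w=[1.0], a_on=[0.85], a_off=[0.85], dt=0.005,
                            band_freqs=[1000.0])
        up = make_step(1, 250, 100, 250, dt=0.005, band_freqs=[1000.0])
        down = Cochleagram(values=1.0 - up.values, band_freqs=[1000.0],
                           dt=0.005)
        on_up = apply_adaptrans(up, p, K=80).on[0]
        off_down = apply_adaptrans(down, p, K=80).off[0]
        np.testing.assert_allclose(on_up, off_down, atol=1e-10)

    def test_band_count_mismatch(self, params):
        stim = make_step(3, 100, 10, 50)
        with pytest.raises(ValueError):
            apply_adaptrans(stim, params)


class TestRectify:
    def test_mixed_signs(self, single_band):
        stim = make_step(1, 120, 20, 80, dt=0.005, band_freqs=[1000.0])
        out = apply_adaptrans(stim, single_band)
        rect = rectify(out)
        assert rect.rectified
        assert np.all(rect.values >= 0)
        pos = out.values > 0
        np.testing.assert_array_equal(rect.values[pos], out.values[pos])
        assert np.all(rect.values[~pos] == 0)

    def test_identity_on_nonnegative(self, single_band):
        x = apply_adaptrans(make_step(1, 50, 0, 50, dt=0.005,
                                      band_freqs=[1000.0]), single_band)
        x.values = np.abs(x.values)
        np.testing.assert_array_equal(rectify(x).values, x.values)


class TestTransferFunction:
    @pytest.mark.parametrize("w", [0.0, 0.3, 0.9])
    @pytest.mark.parametrize("polarity", ["on", "off"])
    def test_dc_gain(self, w, polarity):
        h = transfer_function(w, 0.7, polarity, 1.0)
        assert h == pytest.approx(1 - w, abs=1e-14)

    def test_w_zero_is_allpass(self):
        z = np.exp(1j * np.linspace(0.1, 3.0, 20))
        h = transfer_function(0.0, 0.7, "on", z)
        np.testing.assert_allclose(np.abs(h), 1.0, atol=1e-12)

    def test_pole_guarded(self):
        with pytest.raises(ZeroDivisionError):
            transfer_function(0.5, 0.7, "on", 0.7)

    @pytest.mark.parametrize("polarity", ["on", "off"])
    @pytest.mark.parametrize("w, a", [(0.25, 0.5), (0.75, 0.9), (1.0, 0.8)])
    def test_matches_fft_of_truncated_kernel(self, polarity, w, a):
        # convergence contract: agreement once K comfortably exceeds 5 tau
        tau = tau_from_a(a)
        K = int(np.ceil(10 * tau)) + 1
        pair = build_kernels(w, a, a, K)
        h = pair.h_on if polarity == "on" else pair.h_off
        n_fft = 2048
        fft_mag = np.abs(np.fft.rfft(h, n_fft))
        omega = 2 * np.pi * np.arange(len(fft_mag)) / n_fft
        analytic = np.abs(transfer_function(w, a, polarity, np.exp(1j * omega)))
        np.testing.assert_allclose(fft_mag, analytic, atol=1e-3)


class TestBode:
    def test_high_pass_trend(self):
        mag, _ = bode_curves(0.75, 0.9, "on", [1.0, 40.0, 90.0], dt=0.005)
        assert mag[0] < mag[1] < mag[2]

    def test_fully_transient_polarities_have_equal_magnitude(self):
        freqs = np.linspace(0.5, 99.0, 40)
        mag_on, _ = bode_curves(1.0, 0.8, "on", freqs, dt=0.005)
        mag_off, _ = bode_curves(1.0, 0.8, "off", freqs, dt=0.005)
        np.testing.assert_allclose(mag_on, mag_off, atol=1e-10)

    def test_dc_magnitude(self):
        mag, _ = bode_curves(0.75, 0.9, "on", [0.0], dt=0.005)
        assert mag[0] == pytest.approx(20 * np.log10(0.25), abs=1e-10)

    def test_nyquist_rejected(self):
        with pytest.raises(ValueError):
            bode_curves(0.5, 0.9, "on", [100.0], dt=0.005)


class TestOffsetAmplitude:
    def test_endpoints(self):
        assert offset_amplitude_closed_form(1, 0.8) == pytest.approx(0.2)
        assert offset_amplitude_closed_form(10000, 0.8) == pytest.approx(1.0)

    def test_strictly_increasing_and_saturating(self):
        T = np.arange(1, 200)
        amp = offset_amplitude_closed_form(T, 0.95)
        assert np.all(np.diff(amp) > 0)
        assert amp[-1] < 1.0

    def test_duration_below_one_rejected(self):
        with pytest.raises(ValueError):
            offset_amplitude_closed_form(0, 0.8)

    @pytest.mark.parametrize("a", [0.5, 0.9, 0.99])
    @pytest.mark.parametrize("T_step", [1, 3, 17, 120])
    def test_matches_direct_convolution(self, a, T_step):
        # brute-force oracle: convolve the (effectively untruncated) OFF
        # kernel with a length-T step and read the first post-offset sample
        w = 0.4
        K = max(T_step + 2, int(20 * tau_from_a(a)))
        pair = build_kernels(w, a, a, K)
        stim = np.concatenate([np.ones(T_step), np.zeros(5)])
        padded = np.concatenate([np.zeros(K - 1), stim])
        off = np.convolve(padded, pair.h_off, mode="valid")
        assert off[T_step] == pytest.approx(
            offset_amplitude_closed_form(T_step, a), abs=1e-6)


class TestICAdaptation:
    def test_step_profile(self):
        stim = make_step(1, 300, 50, 250, dt=0.005, band_freqs=[1000.0])
        out = ic_adaptation(stim)
        assert out.shape == (1, 300)
        assert out[0, 50] == pytest.approx(1.0, abs=1e-10)
        assert out[0, 249] == pytest.approx(0.0, abs=1e-6)  # 1 - w with w = 1

    def test_offsets_discarded(self):
        stim = make_step(1, 300, 10, 100, dt=0.005, band_freqs=[1000.0])
        out = ic_adaptation(stim)
        assert np.all(out >= 0)
        assert np.all(out[0, 100:] == 0)  # negative deflection rectified away

    def test_silence(self, band_freqs):
        stim = Cochleagram(values=np.zeros((8, 80)), band_freqs=band_freqs,
                           dt=0.005)
        assert np.all(ic_adaptation(stim) == 0)


class TestParamsContainer:
    def test_length_consistency_enforced(self):
        with pytest.raises(ValueError):
            AdapTransParams(w=[0.5, 0.5], a_on=[0.6], a_off=[0.6], dt=0.005,
                            band_freqs=[1000.0])

    @pytest.mark.parametrize("bad", [dict(w=[-0.1]), dict(w=[1.1]),
                                     dict(a_on=[0.0]), dict(a_off=[1.0])])
    def test_range_violations_rejected(self, bad):
        kwargs = dict(w=[0.5], a_on=[0.6], a_off=[0.6], dt=0.005,
                      band_freqs=[1000.0])
        kwargs.update(bad)
        with pytest.raises(ValueError):
            AdapTransParams(**kwargs)

    def test_standard_initialization(self, band_freqs):
        p = AdapTransParams.from_frequencies(band_freqs, dt=0.005)
        assert np.all(p.w == 0.75)
        np.testing.assert_allclose(
            p.tau_on, init_time_constants(band_freqs, 0.005), rtol=1e-12)
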