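"""Log-Gabor bank and phase congruency unit/property tests."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from pclung.pc import (
    PCParams,
    bandwidth_octaves,
    build_filter_bank,
    channel_responses,
    log_gabor_transfer,
    noise_threshold,
    phase_congruency_map,
    phase_deviation,
    rayleigh_threshold,
    sigmoid_weight,
)


class TestLogGaborTransfer:
    def test_unit_gain_at_centre(self):
        assert log_gabor_transfer(0.1, 0.1, 0.55) == pytest.approx(1.0)

    def test_zero_dc(self):
        assert log_gabor_transfer(0.0, 0.1, 0.55) == 0.0

    def test_half_width_point(self):
        # at w = sigma * w0 the log deviates by log(sigma): gain exp(-1/2)
        assert log_gabor_transfer(0.055, 0.1, 0.55) == pytest.approx(np.exp(-0.5))

    def test_invalid_centre_frequency(self):
        with pytest.raises(ValueError):
            log_gabor_transfer(0.1, 0.0, 0.55)


class TestBandwidthOctaves:
    def test_sigma_055_is_about_two_octaves(self):
        assert round(bandwidth_octaves(0.55)) == 2
        assert bandwidth_octaves(0.55) == pytest.approx(2.03, abs=0.005)

    def test_sigma_074(self):
        assert bandwidth_octaves(0.74) == pytest.approx(1.02, abs=0.005)

    def test_narrow_limit(self):
        assert bandwidth_octaves(0.999) == pytest.approx(0.0, abs=0.01)

    @pytest.mark.parametrize("sigma", [0.0, 1.0, 1.5])
    def test_invalid_sigma(self, sigma):
        with pytest.raises(ValueError):
            bandwidth_octaves(sigma)


class TestFilterBank:
    def test_channel_count_and_range(self):
        bank = build_filter_bank(PCParams(), (64, 64))
        assert bank.n_channels == 30
        assert bank.gains.shape[:2] == (5, 6)
        assert bank.gains.min() >= 0 and bank.gains.max() <= 1.0

    def test_dc_gain_zero_everywhere(self):
        bank = build_filter_bank(PCParams(n=3, o=4), (32, 32))
        assert np.all(bank.gains[:, :, 0, 0] == 0.0)

    def test_wavelengths_geometric(self):
        p = PCParams(lambda_min=8, alpha=3)
        ratios = p.wavelengths[1:] / p.wavelengths[:-1]
        assert np.allclose(ratios, 3.0)

    def test_lambda_min_below_nyquist_rejected(self):
        with pytest.raises(ValueError):
            PCParams(lambda_min=2.0)

    def test_oversized_wavelength_warns(self):
        with pytest.warns(UserWarning):
            build_filter_bank(PCParams(), (32, 32))

    def test_sinusoid_gain_matches_transfer_function(self):
        # a single-scale bank responds to on-grid sinusoids at the channel
        # orientation with the analytic radial gain ratio
        n = 64
        p = PCParams(n=1, o=6, lambda_min=8, alpha=3)
        bank = build_filter_bank(p, (n, n))
        x = np.arange(n)
        resp_amps = []
        freqs = [8 / n, 16 / n]  # on-band (= 1/lambda_min) and off-band
        for f in freqs:
            img = np.cos(2 * np.pi * f * x)[None, :].repeat(n, axis=0)
            amp = np.abs(channel_responses(img, bank).responses[0, 0])
            resp_amps.append(amp.mean())
        expected = log_gabor_transfer(freqs[0], 1 / 8, p.sigma) / log_gabor_transfer(
            freqs[1], 1 / 8, p.sigma
        )
        assert resp_amps[0] / resp_amps[1] == pytest.approx(expected, rel=1e-6)


class TestChannelResponses:
    def test_zero_image(self):
        bank = build_filter_bank(PCParams(n=2, o=2, lambda_min=4, alpha=2), (16, 16))
        resp = channel_responses(np.zeros((16, 16)), bank)
        assert np.all(resp.amplitude == 0)
        assert np.all(resp.phase == 0)

    def test_linearity_in_amplitude(self, rng):
        bank = build_filter_bank(PCParams(n=2, o=2, lambda_min=4, alpha=2), (16, 16))
        img = rng.normal(size=(16, 16))
        r1 = channel_responses(img, bank)
        r2 = channel_responses(3.0 * img, bank)
        assert np.allclose(r2.amplitude, 3.0 * r1.amplitude)
        nz = r1.amplitude > 1e-12
        assert np.allclose(r2.phase[nz], r1.phase[nz])

    def test_shape_mismatch(self):
        bank = build_filter_bank(PCParams(n=2, o=2, lambda_min=4, alpha=2), (16, 16))
        with pytest.raises(ValueError):
            channel_responses(np.zeros((8, 8)), bank)

    def test_matches_circular_convolution_oracle(self, rng):
        # frequency-domain filtering == direct circular convolution with
        # the channel's complex spatial kernel
        n = 32
        bank = build_filter_bank(PCParams(n=2, o=3, lambda_min=4, alpha=2), (n, n))
        img = rng.normal(size=(n, n))
        resp = channel_responses(img, bank).responses
        for (i, j) in [(0, 0), (1, 2)]:
            kernel = np.fft.ifft2(bank.gains[i, j])
            direct = np.zeros((n, n), dtype=complex)
            for r in range(n):
                for c in range(n):
                    direct += img[r, c] * np.roll(np.roll(kernel, r, axis=0), c, axis=1)
            assert np.abs(direct - resp[i, j]).max() < 1e-8


class TestPhaseDeviation:
    @pytest.mark.parametrize(
        "delta,expected",
        [(0.0, 1.0), (np.pi / 2, -1.0), (-np.pi / 2, -1.0), (np.pi / 4, 0.0)],
    )
    def test_values(self, delta, expected):
        assert phase_deviation(delta, 0.0) == pytest.approx(expected, abs=1e-12)

    @given(st.floats(-np.pi, np.pi))
    def test_range_and_symmetry(self, d):
        v = phase_deviation(d, 0.0)
        assert -np.sqrt(2) - 1e-12 <= v <= 1.0 + 1e-12
        assert v == pytest.approx(phase_deviation(-d, 0.0), abs=1e-12)


class TestNoiseThreshold:
    def test_k_zero_returns_rayleigh_mean(self, rng):
        amps = rng.rayleigh(2.0, size=1000)
        t0 = rayleigh_threshold(amps, 0.0)
        t2 = rayleigh_threshold(amps, 2.0)
        assert t2 > t0 > 0

    def test_zero_amplitudes(self):
        assert rayleigh_threshold(np.zeros(100), 2.0) == 0.0

    def test_monte_carlo_recovers_rayleigh_mean(self, rng):
        s = 1.7
        amps = rng.rayleigh(s, size=10_000)
        mu_est = rayleigh_threshold(amps, 0.0)
        assert mu_est == pytest.approx(s * np.sqrt(np.pi / 2), rel=0.05)

    def test_orientation_accessor(self, rng):
        bank = build_filter_bank(PCParams(n=2, o=2, lambda_min=4, alpha=2), (32, 32))
        resp = channel_responses(rng.normal(size=(32, 32)), bank)
        t = noise_threshold(resp, 2.0, 1)
        assert t == rayleigh_threshold(np.abs(resp.responses[0, 1]), 2.0)


class TestSigmoidWeight:
    def test_midpoint(self):
        assert sigmoid_weight(0.3, 50.0, 0.3) == pytest.approx(0.5)

    def test_saturation(self):
        assert sigmoid_weight(1.0, 50.0, 0.3) == pytest.approx(1.0, abs=1e-15)
        assert sigmoid_weight(0.0, 50.0, 0.3) == pytest.approx(3.06e-7, rel=0.01)

    @given(st.floats(0, 1), st.floats(0, 1))
    def test_monotone_in_spread_and_cutoff(self, s, c):
        assert sigmoid_weight(s + 0.01, 50.0, c) >= sigmoid_weight(s, 50.0, c)
        assert sigmoid_weight(s, 50.0, c + 0.01) <= sigmoid_weight(s, 50.0, c)


class TestPhaseCongruencyMap:
    def test_constant_image_is_zero(self):
        result = phase_congruency_map(np.full((32, 32), 7.0))
        assert np.all(result.pc == 0.0)

    def test_range(self, rng):
        img = rng.uniform(0, 4095, size=(64, 64))
        pc = phase_congruency_map(img).pc
        assert pc.min() >= 0.0 and pc.max() <= 1.0

    def test_step_edge_localization(self):
        # vertical step at column 32: per-row PC maxima sit on the edge
        step = np.zeros((64, 64))
        step[:, 32:] = 1.0
        params = PCParams(n=4, o=6, lambda_min=4, alpha=2.0, k=2.0)
        cols = np.argmax(phase_congruency_map(step, params).pc, axis=1)
        assert np.all((cols >= 31) & (cols <= 33))
        # same localization with noise compensation off and generic cut-off
        params = PCParams(n=4, o=6, lambda_min=4, alpha=2.0, c=0.4, k=0.0)
        cols = np.argmax(phase_congruency_map(step, params, noise_mode="none").pc, axis=1)
        assert np.all((cols >= 31) & (cols <= 33))

    def test_brightness_contrast_invariance(self, rng):
        img = rng.uniform(0, 100, size=(64, 64))
        params = PCParams(k=0.0)
        ref = phase_congruency_map(img, params).pc
        for a in (0.5, 2.0, 10.0):
            other = phase_congruency_map(a * img + 13.0, params).pc
            assert np.abs(other - ref).max() < 1e-6

    def test_nonfinite_input_rejected(self):
        img = np.zeros((16, 16))
        img[3, 3] = np.nan
        with pytest.raises(ValueError):
            phase_congruency_map(img)

    def test_channel_energies_shape(self, rng):
        result = phase_congruency_map(rng.normal(size=(32, 32)))
        assert result.channel_energies.shape == (30,)
        assert np.all(result.channel_energies >= 0)

    @given(st.integers(0, 2**31 - 1))
    def test_range_property_random_images(self, seed):
        img = np.random.default_rng(seed).normal(size=(24, 24))
        params = PCParams(n=3, o=4, lambda_min=4, alpha=2)
        pc = phase_congruency_map(img, params).pc
        assert pc.min() >= 0.0 and pc.max() <= 1.0
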