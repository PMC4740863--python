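"""Frequency-to-time conversion, clutter removal, normalisation, noise."""

import numpy as np
import pytest

import mwbrain as m
from mwbrain.sigproc import (
    NoiseConfig,
    PulseSpec,
    TimeSignals,
    add_noise,
    gaussian_pulse,
    pulse_spectrum,
)

SWEEP = m.FrequencySweep()


def _dataset(s11, n_pos=None):
    n_pos = n_pos or s11.shape[0]
    geom = m.make_circular_scan(100.0, n_pos)
    return m.ReflectionDataset(s11=s11, sweep=SWEEP, geometry=geom)


def _forward_band_dft(signals: TimeSignals):
    """Independent forward DFT back onto the band frequencies."""
    k = signals.n_samples
    t = signals.time_axis
    f = signals.sweep.frequencies
    ker = np.exp(-2j * np.pi * np.outer(f, t))
    m_ = signals.sweep.n_samples
    return (m_ / k) * signals.samples @ ker.T


class TestToTimeDomain:
    def test_all_pass_spectrum_peaks_at_zero(self):
        data = _dataset(np.ones((4, SWEEP.n_samples), dtype=complex))
        ts = m.to_time_domain(data)
        assert np.argmax(np.abs(ts.samples[0])) == 0

    def test_single_echo_peak_position(self):
        k = 4 * SWEEP.n_samples
        dt = 1.0 / (k * SWEEP.df)
        tau0 = 173 * dt  # on the zero-padded grid
        s = np.exp(-2j * np.pi * SWEEP.frequencies * tau0)
        data = _dataset(np.tile(s, (4, 1)))
        ts = m.to_time_domain(data)
        assert np.argmax(np.abs(ts.samples[0])) == 173

    def test_forward_dft_round_trip(self):
        rng = np.random.default_rng(5)
        s11 = rng.standard_normal((3, SWEEP.n_samples)) + 1j * rng.standard_normal(
            (3, SWEEP.n_samples)
        )
        data = _dataset(s11)
        ts = m.to_time_domain(data)
        back = _forward_band_dft(ts)
        assert np.max(np.abs(back - s11)) / np.max(np.abs(s11)) < 1e-10

    def test_k_too_small_rejected(self):
        data = _dataset(np.ones((3, SWEEP.n_samples), dtype=complex))
        with pytest.raises(ValueError):
            m.to_time_domain(data, k_samples=10)


def _time_signals(samples):
    geom = m.make_circular_scan(100.0, samples.shape[0])
    return TimeSignals(samples=samples.astype(complex), dt=1e-10, geometry=geom, sweep=SWEEP)


class TestAdjacentAverageSubtract:
    def test_identical_baselines_cancel(self):
        base = np.sin(np.linspace(0, 20, 256))
        ts = _time_signals(np.tile(base, (6, 1)))
        out = m.adjacent_average_subtract(ts)
        assert np.max(np.abs(out.samples)) < 1e-12

    def test_unique_echo_retained_three_position_reference(self):
        k = 256
        t = np.arange(k)
        base = np.exp(-((t - 60.0) ** 2) / 30.0)
        echo = 0.2 * np.exp(-((t - 150.0) ** 2) / 10.0)
        sig = np.tile(base, (3, 1))
        sig[0] += echo
        ts = _time_signals(sig)
        out = m.adjacent_average_subtract(ts, align=False)
        # brute-force 3-position ring reference
        expect0 = sig[0] - 0.5 * (sig[1] + sig[2])
        assert np.allclose(out.samples[0].real, expect0, atol=1e-12)
        assert np.max(np.abs(out.samples[0])) >= 0.9 * 0.2
        # baseline-only content cancels
        assert np.max(np.abs(out.samples[0, :120])) < 1e-12

    def test_woody_alignment_reduces_shifted_baseline_residual(self):
        k = 256
        t = np.arange(k)
        base = np.exp(-((t - 120.0) ** 2) / 25.0)
        shifts = [0, 2, -2, 2, -2, 0]
        sig = np.stack([np.roll(base, s) for s in shifts])
        ts = _time_signals(sig)
        e_aligned = np.sum(np.abs(m.adjacent_average_subtract(ts, align=True).samples) ** 2)
        e_plain = np.sum(np.abs(m.adjacent_average_subtract(ts, align=False).samples) ** 2)
        assert e_aligned < e_plain

    def test_linearity_without_alignment(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal((5, 128))
        y = rng.standard_normal((5, 128))
        f = lambda z: m.adjacent_average_subtract(_time_signals(z), align=False).samples
        lhs = f(2.0 * x + 3.0 * y)
        rhs = 2.0 * f(x) + 3.0 * f(y)
        assert np.allclose(lhs, rhs, atol=1e-12)

    def test_energy_bound(self):
        rng = np.random.default_rng(4)
        x = rng.standard_normal((8, 200))
        out = m.adjacent_average_subtract(_time_signals(x), align=False)
        assert np.sum(np.abs(out.samples) ** 2) <= 4.0 * np.sum(x**2)

    def test_too_few_positions(self):
        geom = m.make_circular_scan(100.0, 3)
        ts = TimeSignals(
            samples=np.ones((3, 64), complex), dt=1e-10, geometry=geom, sweep=SWEEP
        )
        # three positions is the minimum; two-row input cannot even be built
        m.adjacent_average_subtract(ts)
        with pytest.raises(ValueError):
            m.adjacent_average_subtract(
                TimeSignals(samples=np.ones((2, 64), complex), dt=1e-10,
                            geometry=geom, sweep=SWEEP)
            )


class TestNormalizeGain:
    def test_unit_peak(self):
        sig = np.zeros((3, 64))
        sig[:, 10] = 0.2
        out = m.normalize_gain(_time_signals(sig))
        assert np.max(np.abs(out.samples), axis=1) == pytest.approx(1.0)

    def test_all_zero_position_flagged(self):
        sig = np.zeros((3, 64))
        sig[0, 5] = 1.0
        out = m.normalize_gain(_time_signals(sig))
        assert list(out.zero_positions) == [1, 2]
        assert np.all(out.samples[1] == 0)

    def test_shape_preserved(self):
        rng = np.random.default_rng(9)
        sig = rng.standard_normal((4, 100))
        ts = _time_signals(sig)
        out = m.normalize_gain(ts)
        peaks = np.max(np.abs(sig), axis=1)
        assert np.allclose(out.samples * peaks[:, None], sig, atol=1e-12)


class TestGaussianPulse:
    def test_envelope_peak_at_center(self):
        spec = PulseSpec()
        t = np.linspace(0, 20e-9, 2001)
        g = gaussian_pulse(spec, t)
        env_peak = np.argmax(np.abs(g))
        assert abs(env_peak - 1000) <= 2

    def test_spectrum_centred_on_carrier(self):
        spec = PulseSpec()
        dt = 1e-11
        t = np.arange(4096) * dt
        g = gaussian_pulse(spec, t)
        f = np.fft.rfftfreq(len(t), dt)
        mag = np.abs(np.fft.rfft(g))
        assert f[np.argmax(mag)] == pytest.approx(1.6e9, abs=f[1])

    def test_minus_10db_extent_covers_band(self):
        spec = PulseSpec()
        dt = 1e-11
        t = np.arange(8192) * dt
        g = gaussian_pulse(spec, t)
        f = np.fft.rfftfreq(len(t), dt)
        mag = np.abs(np.fft.rfft(g))
        thresh = mag.max() * 10 ** (-0.5)
        band = f[mag >= thresh]
        assert band.min() <= 0.75e9 and band.max() >= 2.55e9

    def test_short_grid_rejected(self):
        with pytest.raises(ValueError):
            gaussian_pulse(PulseSpec(), np.linspace(0, 1e-9, 100))

    def test_closed_form_spectrum_matches_fft(self):
        spec = PulseSpec()
        dt = 1e-11
        t = np.arange(8192) * dt
        g = gaussian_pulse(spec, t)
        f = np.fft.rfftfreq(len(t), dt)
        mag = np.abs(np.fft.rfft(g))
        sel = (f > 0.8e9) & (f < 2.5e9)
        ratio = mag[sel] / mag.max()
        assert np.allclose(ratio, pulse_spectrum(spec, f[sel]), atol=0.02)


class TestAddNoise:
    def test_infinite_snr_unchanged(self):
        rng = np.random.default_rng(1)
        s11 = rng.standard_normal((4, SWEEP.n_samples)) + 0j
        data = _dataset(s11)
        out = add_noise(data, NoiseConfig(snr_db=np.inf, seed=0))
        assert np.array_equal(out.s11, s11)

    def test_deterministic_under_seed(self):
        data = _dataset(np.ones((4, SWEEP.n_samples), complex))
        a = add_noise(data, NoiseConfig(snr_db=10.0, seed=42))
        b = add_noise(data, NoiseConfig(snr_db=10.0, seed=42))
        assert np.array_equal(a.s11, b.s11)

    def test_empirical_snr_within_half_db(self):
        rng = np.random.default_rng(6)
        s11 = rng.standard_normal((32, SWEEP.n_samples)) + 1j * rng.standard_normal(
            (32, SWEEP.n_samples)
        )
        data = _dataset(s11)
        out = add_noise(data, NoiseConfig(snr_db=20.0, seed=7))
        p_sig = np.mean(np.abs(s11) ** 2)
        p_noise = np.mean(np.abs(out.s11 - s11) ** 2)
        assert 10 * np.log10(p_sig / p_noise) == pytest.approx(20.0, abs=0.5)
        assert out.snr_db == 20.0
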