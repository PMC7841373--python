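"""Signal-primitive correctness against closed forms and brute force."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import signal as sps

from swimseg.errors import (
    DegenerateInputError,
    InvalidInputError,
    InvalidParameterError,
)
from swimseg.primitives import (
    TimeSeries,
    derivative,
    detect_extrema,
    detect_sharp_change,
    emd,
    envelope,
    instantaneous_energy,
    lowpass,
    power_spectrum,
    principal_components,
    _strict_peak_indices,
)

FS = 500.0


def ts(values, fs=FS):
    return TimeSeries(np.asarray(values, dtype=float), fs)


def sine(freq, duration, fs=FS, amp=1.0, phase=0.0):
    t = np.arange(int(duration * fs)) / fs
    return ts(amp * np.sin(2 * np.pi * freq * t + phase), fs)


class TestLowpass:
    def test_dc_gain_is_one(self):
        out = lowpass(ts(np.full(2000, 3.7)), fc=10.0)
        assert np.max(np.abs(out.values - 3.7)) < 1e-9

    def test_stopband_gain_matches_squared_butterworth(self):
        # forward-backward filtering applies |H|²; compare the 50 Hz sine
        # attenuation with the analytic Butterworth magnitude
        s = sine(50.0, 4.0)
        out = lowpass(s, fc=10.0, order=2)
        b, a = sps.butter(2, 10.0, fs=FS)
        _, h = sps.freqz(b, a, worN=[50.0], fs=FS)
        expected = np.abs(h[0]) ** 2
        measured = np.max(np.abs(out.values[500:-500]))
        assert measured == pytest.approx(expected, rel=0.05)

    def test_passband_sine_preserved(self):
        out = lowpass(sine(1.0, 4.0), fc=10.0)
        assert np.max(out.values[500:-500]) == pytest.approx(1.0, rel=0.01)

    def test_cutoff_above_nyquist_rejected(self):
        with pytest.raises(InvalidParameterError):
            lowpass(sine(1.0, 1.0), fc=FS)

    def test_idempotent_on_band_limited_signal(self):
        once = lowpass(sine(1.0, 4.0), fc=10.0)
        twice = lowpass(once, fc=10.0)
        core = slice(500, -500)
        assert np.max(np.abs(twice.values[core] - once.values[core])) < 0.01


class TestDerivative:
    def test_constant_gives_zero_and_ramp_gives_slope(self):
        assert np.allclose(derivative(ts(np.full(100, 2.0))).values, 0.0)
        t = np.arange(1000) / FS
        d = derivative(ts(3.5 * t))
        assert np.max(np.abs(d.values[1:-1] - 3.5)) < 1e-9

    def test_sine_derivative_amplitude(self):
        d = derivative(sine(1.0, 4.0))
        assert np.max(d.values) == pytest.approx(2 * np.pi, rel=1e-3)

    def test_too_short_rejected(self):
        with pytest.raises(InvalidInputError):
            derivative(ts([1.0]))


class TestDetectExtrema:
    def test_monotone_ramp_has_no_extrema(self):
        assert detect_extrema(ts(np.linspace(0, 1, 500)), 0.0) == []

    def test_sine_peak_times(self):
        events = detect_extrema(sine(2.0, 2.0), 0.5, "peak")
        assert [e.time for e in events] == pytest.approx(
            [0.125, 0.625, 1.125, 1.625], abs=2 / FS
        )

    def test_threshold_above_max_empty(self):
        assert detect_extrema(sine(2.0, 1.0), 2.0, "peak") == []

    def test_trough_polarity_negative_threshold(self):
        events = detect_extrema(sine(2.0, 1.0), -0.5, "trough")
        assert all(e.amplitude <= -0.5 for e in events)
        assert [e.time for e in events] == pytest.approx([0.375, 0.875],
                                                         abs=2 / FS)

    @settings(deadline=None, max_examples=1000, derandomize=True)
    @given(st.lists(st.floats(-10, 10), min_size=3, max_size=60,
                    unique=True),
           st.floats(-5, 5))
    def test_matches_brute_force_neighbor_scan(self, values, threshold):
        s = ts(values, fs=10.0)
        got = [(e.time, e.amplitude) for e in detect_extrema(s, threshold)]
        expected = [
            (i / 10.0, values[i])
            for i in range(1, len(values) - 1)
            if values[i - 1] < values[i] > values[i + 1]
            and values[i] >= threshold
        ]
        assert got == expected


class TestSharpChange:
    def test_constant_input_no_events(self):
        assert detect_sharp_change(ts(np.full(4000, 1.0))) == []

    def test_logistic_step_yields_one_rise_at_center(self):
        t = np.arange(int(10 * FS)) / FS
        s = ts(1.0 / (1.0 + np.exp(-(t - 5.0) / 0.1)))
        events = detect_sharp_change(s, 0.3)
        rises = [e for e in events if e.polarity == "rise"]
        assert len(rises) == 1
        assert rises[0].time == pytest.approx(5.0, abs=0.05)

    def test_falling_step_yields_fall_at_center(self):
        t = np.arange(int(10 * FS)) / FS
        s = ts(1.0 - 1.0 / (1.0 + np.exp(-(t - 5.0) / 0.1)))
        events = detect_sharp_change(s, 0.3)
        falls = [e for e in events if e.polarity == "fall"]
        assert len(falls) == 1
        assert falls[0].time == pytest.approx(5.0, abs=0.05)

    def test_sign_flip_swaps_polarities(self):
        rng = np.random.default_rng(3)
        t = np.arange(int(8 * FS)) / FS
        s = np.tanh((t - 3) * 4) + 0.1 * rng.normal(size=t.size)
        a = detect_sharp_change(ts(s), 0.3)
        b = detect_sharp_change(ts(-s), 0.3)
        swap = {"rise": "fall", "fall": "rise"}
        assert [(e.time, e.polarity) for e in a] == [
            (e.time, swap[e.polarity]) for e in b
        ]


class TestEnvelope:
    def test_constant_series(self):
        out = envelope(ts(np.full(4000, 2.5)), 1.0)
        assert np.max(np.abs(out.values[600:-600] - 2.5)) < 1e-6

    def test_sine_about_mean_tracks_m_plus_a(self):
        t = np.arange(int(8 * FS)) / FS
        s = ts(1.5 + 0.8 * np.sin(2 * np.pi * 2.0 * t))
        out = envelope(s, 1.0)
        core = out.values[1000:-1000]
        assert np.max(np.abs(core - 2.3)) < 0.05 * 2.3

    def test_zero_series(self):
        out = envelope(ts(np.zeros(2000)), 1.0)
        assert np.max(np.abs(out.values)) < 1e-9

    def test_short_window_rejected(self):
        with pytest.raises(InvalidParameterError):
            envelope(ts(np.zeros(100)), window=1e-4)


class TestPrincipalComponents:
    def test_single_axis_variance(self):
        rng = np.random.default_rng(0)
        x = np.zeros((200, 3))
        x[:, 2] = rng.normal(size=200)
        comps, ratios = principal_components(x)
        assert abs(comps[0][2]) == pytest.approx(1.0, abs=1e-9)
        assert ratios[0] == pytest.approx(1.0)

    def test_matches_eigendecomposition_of_known_covariance(self):
        rng = np.random.default_rng(1)
        cov = np.array([[4.0, 1.0, 0.0], [1.0, 2.0, 0.5], [0.0, 0.5, 1.0]])
        x = rng.multivariate_normal(np.zeros(3), cov, size=20000)
        comps, ratios = principal_components(x)
        xc = x - x.mean(axis=0)
        w, v = np.linalg.eigh(xc.T @ xc / (len(x) - 1))
        order = np.argsort(w)[::-1]
        for k in range(3):
            assert abs(comps[k] @ v[:, order[k]]) == pytest.approx(1.0, abs=1e-6)
        assert ratios.sum() == pytest.approx(1.0)

    def test_orthonormality(self):
        rng = np.random.default_rng(2)
        comps, _ = principal_components(rng.normal(size=(100, 3)))
        assert np.allclose(comps @ comps.T, np.eye(3), atol=1e-9)

    def test_rank_zero_rejected(self):
        with pytest.raises(DegenerateInputError):
            principal_components(np.ones((10, 3)))


class TestPowerSpectrum:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_parseval_identity(self, seed):
        rng = np.random.default_rng(seed)
        s = ts(rng.normal(size=4096))
        freqs, power = power_spectrum(s)
        df = freqs[1] - freqs[0]
        assert np.sum(power) * df == pytest.approx(
            np.mean(s.values**2), rel=1e-6
        )

    def test_sine_dominant_bin(self):
        freqs, power = power_spectrum(sine(1.2, 10.0))
        assert abs(freqs[np.argmax(power)] - 1.2) <= freqs[1] - freqs[0]

    def test_three_second_window_resolution(self):
        # a 3 s window resolves 1/3 Hz, finer than the 0.35 Hz requirement
        freqs, _ = power_spectrum(sine(1.0, 3.0))
        assert freqs[1] - freqs[0] == pytest.approx(1 / 3, rel=1e-9)
        assert freqs[1] - freqs[0] <= 0.35


class TestEmd:
    def test_reconstruction_identity(self):
        rng = np.random.default_rng(4)
        t = np.arange(int(6 * FS)) / FS
        s = ts(np.sin(2 * np.pi * 5 * t) + np.sin(2 * np.pi * 0.5 * t)
               + 0.1 * rng.normal(size=t.size))
        imfs, resid = emd(s)
        recon = sum(m.values for m in imfs) + resid.values
        scale = np.max(np.abs(s.values))
        assert np.max(np.abs(recon - s.values)) < 1e-8 * scale

    def test_modes_ordered_fast_to_slow(self):
        t = np.arange(int(10 * FS)) / FS
        s = ts(np.sin(2 * np.pi * 5 * t) + np.sin(2 * np.pi * 0.5 * t))
        imfs, _ = emd(s, max_imfs=4)
        assert len(imfs) >= 2

        def centroid(m):
            f, p = power_spectrum(m)
            return np.sum(f * p) / np.sum(p)

        assert centroid(imfs[0]) > centroid(imfs[1])

    def test_constant_input_yields_no_imfs(self):
        imfs, resid = emd(ts(np.full(100, 1.5)))
        assert imfs == []
        assert np.allclose(resid.values, 1.5)


class TestInstantaneousEnergy:
    def test_zero_series(self):
        assert np.allclose(instantaneous_energy(ts(np.zeros(100))).values, 0.0)

    def test_unit_sine_energy_near_one(self):
        en = instantaneous_energy(sine(2.0, 6.0))
        core = en.values[500:-500]
        assert np.max(np.abs(core - 1.0)) < 0.02

    def test_quadratic_homogeneity(self):
        s = sine(2.0, 4.0)
        e1 = instantaneous_energy(s)
        e2 = instantaneous_energy(s.map(2 * s.values))
        assert np.allclose(e2.values, 4 * e1.values, rtol=1e-9)
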