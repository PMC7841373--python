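"""Single-axis signal primitives shared by all macro/micro detectors.

These are the common processing blocks of the analysis: zero-phase Butterworth
low-pass filtering, numerical differentiation, threshold-based extremum
detection, derivative-based sharp-change detection, amplitude envelopes,
principal components, single-sided power spectra, empirical mode decomposition
(EMD), and the instantaneous energy of the analytic signal.

All operations act on :class:`TimeSeries` — a uniformly sampled scalar series
with an explicit sampling rate (acceleration in g, angular velocity in °/s).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
from scipy import signal as sps
from scipy.interpolate import CubicSpline

from .errors import DegenerateInputError, InvalidInputError, InvalidParameterError

Polarity = Literal["peak", "trough", "rise", "fall"]

__all__ = [
    "TimeSeries",
    "DetectedEvent",
    "lowpass",
    "derivative",
    "detect_extrema",
    "detect_sharp_change",
    "envelope",
    "moving_average",
    "principal_components",
    "power_spectrum",
    "emd",
    "instantaneous_energy",
]


@dataclass(frozen=True)
class TimeSeries:
    """A uniformly sampled scalar time series.

    Parameters
    ----------
    values : ndarray
        Sample values (g for acceleration, °/s for angular velocity).
    fs : float
        Sampling rate in Hz. Must be positive.
    t0 : float
        Time of the first sample in seconds.
    """

    values: np.ndarray
    fs: float
    t0: float = 0.0

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if self.fs <= 0:
            raise InvalidParameterError("sampling rate must be positive")
        if v.ndim != 1 or v.size < 1:
            raise InvalidInputError("TimeSeries requires a 1-D series of length >= 1")
        if not np.all(np.isfinite(v)):
            raise InvalidInputError("TimeSeries values must be finite")

    def __len__(self) -> int:
        return self.values.size

    @property
    def duration(self) -> float:
        return (len(self) - 1) / self.fs

    @property
    def t_end(self) -> float:
        return self.t0 + self.duration

    def times(self) -> np.ndarray:
        return self.t0 + np.arange(len(self)) / self.fs

    def index_of(self, t: float) -> int:
        """Nearest sample index for time ``t`` (clipped to the series)."""
        return int(np.clip(round((t - self.t0) * self.fs), 0, len(self) - 1))

    def time_of(self, i: int) -> float:
        return self.t0 + i / self.fs

    def crop(self, t_start: float, t_end: float) -> "TimeSeries":
        """Sub-series covering [t_start, t_end] (clipped to the span)."""
        i0 = self.index_of(t_start)
        i1 = self.index_of(t_end)
        if i1 < i0:
            raise InvalidParameterError("crop window is empty")
        return TimeSeries(self.values[i0 : i1 + 1], self.fs, self.time_of(i0))

    def map(self, values: np.ndarray) -> "TimeSeries":
        """Same time base, new values (must be equal length)."""
        if np.asarray(values).shape != self.values.shape:
            raise InvalidInputError("mapped values must keep the series length")
        return replace(self, values=np.asarray(values, dtype=float))


@dataclass(frozen=True)
class DetectedEvent:
    """A detected extremum or sharp change: time, amplitude and polarity."""

    time: float
    amplitude: float
    polarity: Polarity


def lowpass(ts: TimeSeries, fc: float, order: int = 2) -> TimeSeries:
    """Zero-phase (forward-backward) Butterworth low-pass filter.

    Zero-phase filtering is used so detected event times are not lag-shifted;
    the effective magnitude response is the squared Butterworth gain.
    """
    if order < 1:
        raise InvalidParameterError("filter order must be >= 1")
    if not 0 < fc < ts.fs / 2:
        raise InvalidParameterError(
            f"cutoff {fc} Hz must lie in (0, Nyquist={ts.fs / 2} Hz)"
        )
    sos = sps.butter(order, fc, btype="low", fs=ts.fs, output="sos")
    # padlen guard for very short series
    padlen = min(3 * (2 * order + 1), len(ts) - 1)
    out = sps.sosfiltfilt(sos, ts.values, padlen=padlen)
    return ts.map(out)


def derivative(ts: TimeSeries) -> TimeSeries:
    """Central-difference derivative (units per second); one-sided at edges."""
    if len(ts) < 2:
        raise InvalidInputError("derivative requires length >= 2")
    return ts.map(np.gradient(ts.values) * ts.fs)


def _strict_peak_indices(v: np.ndarray) -> np.ndarray:
    """Local-maximum indices; a flat-topped peak reports its midpoint.

    Identical to the strict neighbor comparison v[i-1] < v[i] > v[i+1]
    whenever adjacent samples differ; exactly sampled extrema (two equal
    samples straddling the continuous peak) are still reported.
    """
    if v.size < 3:
        return np.empty(0, dtype=int)
    idx, _ = sps.find_peaks(v)
    return idx


def detect_extrema(
    ts: TimeSeries,
    threshold: float,
    polarity: Literal["peak", "trough"] = "peak",
    min_prominence: float | None = None,
) -> list[DetectedEvent]:
    """Strict local extrema beyond a threshold, optionally prominence-gated.

    Peaks are strict local maxima with amplitude >= threshold; troughs are
    strict local minima with amplitude <= threshold. A negative threshold on a
    signed signal therefore expresses trough detection. Events are returned in
    time order.
    """
    v = ts.values if polarity == "peak" else -ts.values
    th = threshold if polarity == "peak" else -threshold
    idx = _strict_peak_indices(v)
    idx = idx[v[idx] >= th]
    if min_prominence is not None and idx.size:
        prom = sps.peak_prominences(v, idx)[0]
        idx = idx[prom >= min_prominence]
    return [
        DetectedEvent(ts.time_of(i), float(ts.values[i]), polarity) for i in idx
    ]


def detect_sharp_change(
    ts: TimeSeries,
    fraction: float = 0.3,
    fc: float = 10.0,
    order: int = 2,
) -> list[DetectedEvent]:
    """Abrupt-change detection on the filtered derivative.

    Low-pass filters the series, differentiates, and thresholds the derivative
    at ``± fraction × max(|derivative|)``. Derivative peaks above the positive
    threshold are returned as polarity ``rise``; troughs below the negative
    threshold as ``fall``. A constant input yields no events.
    """
    if not 0 < fraction <= 1:
        raise InvalidParameterError("fraction must lie in (0, 1]")
    if len(ts) < 3:
        return []
    d = derivative(lowpass(ts, fc, order))
    peak = float(np.max(np.abs(d.values)))
    if peak <= 0 or not np.isfinite(peak):
        return []
    # guard against pure numerical residue on (near-)constant input
    if peak < 1e-12 * max(1.0, float(np.max(np.abs(ts.values)))):
        return []
    th = fraction * peak
    rises = detect_extrema(d, th, "peak")
    falls = detect_extrema(d, -th, "trough")
    events = [replace(e, polarity="rise") for e in rises] + [
        replace(e, polarity="fall") for e in falls
    ]
    return sorted(events, key=lambda e: e.time)


def moving_average(ts: TimeSeries, window: float) -> TimeSeries:
    """Centered moving average over ``window`` seconds (edge-replicated)."""
    n = int(round(window * ts.fs))
    if n < 2:
        raise InvalidParameterError("window must span at least 2 samples")
    pad = n // 2
    v = np.pad(ts.values, pad, mode="edge")
    kernel = np.ones(n) / n
    out = np.convolve(v, kernel, mode="same")[pad : pad + len(ts)]
    return ts.map(out)


def envelope(ts: TimeSeries, window: float = 1.0) -> TimeSeries:
    """Amplitude envelope: analytic magnitude about the running mean.

    The running mean over ``window`` is removed, the magnitude of the analytic
    signal of the residual is added back to the running mean, and the result is
    smoothed by the same moving average. For a sinusoid of amplitude A about a
    mean m this tracks m + A.
    """
    rm = moving_average(ts, window)
    resid = ts.values - rm.values
    env = np.abs(sps.hilbert(resid)) + rm.values
    return moving_average(ts.map(env), window)


def principal_components(samples: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Principal axes of an N×3 sample matrix.

    Returns (components, variance_ratios): components[k] is the k-th
    eigenvector of the sample covariance (rows, descending eigenvalue), and
    variance_ratios sum to 1.
    """
    x = np.asarray(samples, dtype=float)
    if x.ndim != 2 or x.shape[1] != 3 or x.shape[0] < 3:
        raise InvalidInputError("principal_components requires an N×3 matrix, N >= 3")
    x = x - x.mean(axis=0)
    cov = x.T @ x / (x.shape[0] - 1)
    w, v = np.linalg.eigh(cov)
    order = np.argsort(w)[::-1]
    w = np.maximum(w[order], 0.0)
    total = w.sum()
    if total <= 0:
        raise DegenerateInputError("sample matrix has zero variance")
    return v[:, order].T, w / total


def power_spectrum(ts: TimeSeries) -> tuple[np.ndarray, np.ndarray]:
    """Single-sided power density spectrum (units²/Hz).

    Boxcar window, no detrending: the discrete Parseval identity
    ``Σ P·Δf = mean(x²)`` holds to numerical precision. Frequency resolution
    is fs/N.
    """
    if len(ts) < 8:
        raise InvalidInputError("power_spectrum requires length >= 8")
    freqs, power = sps.periodogram(
        ts.values, fs=ts.fs, window="boxcar", detrend=False, scaling="density"
    )
    return freqs, power


def amplitude_spectrum(ts: TimeSeries) -> tuple[np.ndarray, np.ndarray]:
    """Single-sided amplitude spectrum in signal units.

    A pure tone of amplitude A that fits the window produces a bin of height
    ≈ A. Used by the technique classifier, whose thresholds are quoted in g.
    """
    if len(ts) < 8:
        raise InvalidInputError("amplitude_spectrum requires length >= 8")
    n = len(ts)
    x = np.fft.rfft(ts.values)
    amp = np.abs(x) * 2.0 / n
    amp[0] /= 2.0
    if n % 2 == 0:
        amp[-1] /= 2.0
    freqs = np.fft.rfftfreq(n, 1.0 / ts.fs)
    return freqs, amp


# ---------------------------------------------------------------------------
# Empirical mode decomposition
# ---------------------------------------------------------------------------


def _spline_envelope(idx: np.ndarray, vals: np.ndarray, n: int) -> np.ndarray | None:
    """Cubic-spline envelope through extrema, mirror-extended at the ends."""
    if idx.size < 2:
        return None
    # mirror the two outermost extrema beyond each boundary
    left_i = -idx[1::-1] if idx.size >= 2 else -idx[::-1]
    left_v = vals[1::-1]
    right_i = 2 * (n - 1) - idx[-1:-3:-1]
    right_v = vals[-1:-3:-1]
    xi = np.concatenate([left_i, idx, right_i])
    yi = np.concatenate([left_v, vals, right_v])
    xi, keep = np.unique(xi, return_index=True)
    yi = yi[keep]
    if xi.size < 2:
        return None
    if xi.size < 4:
        return np.interp(np.arange(n), xi, yi)
    return CubicSpline(xi, yi)(np.arange(n))


def _sift(x: np.ndarray, sd_stop: float, max_sift: int) -> np.ndarray | None:
    """Extract one IMF from x, or None if x has too few extrema."""
    h = x.copy()
    n = x.size
    for _ in range(max_sift):
        maxima = _strict_peak_indices(h)
        minima = _strict_peak_indices(-h)
        if maxima.size + minima.size < 3:
            return None
        upper = _spline_envelope(maxima, h[maxima], n)
        lower = _spline_envelope(minima, h[minima], n)
        if upper is None or lower is None:
            return None
        mean = 0.5 * (upper + lower)
        h_new = h - mean
        denom = np.sum(h**2)
        if denom <= 0:
            return None
        sd = float(np.sum((h - h_new) ** 2) / denom)
        h = h_new
        if sd < sd_stop:
            break
    return h


def emd(
    ts: TimeSeries,
    max_imfs: int = 8,
    sd_stop: float = 0.2,
    max_sift: int = 50,
) -> tuple[list[TimeSeries], TimeSeries]:
    """Empirical mode decomposition into intrinsic mode functions.

    Standard sifting with the standard-deviation stop criterion (default 0.2)
    and mirror boundary extension. IMFs are ordered fast to slow and the
    completeness identity ``Σ IMFs + residual = input`` holds exactly because
    the residual is defined by subtraction.

    A constant (or extrema-free) input yields no IMFs and the input as residual.
    """
    if max_imfs < 1:
        raise InvalidParameterError("max_imfs must be >= 1")
    if len(ts) < 16:
        raise InvalidInputError("emd requires length >= 16")
    x = ts.values.astype(float).copy()
    imfs: list[TimeSeries] = []
    resid = x
    for _ in range(max_imfs):
        imf = _sift(resid, sd_stop, max_sift)
        if imf is None:
            break
        imfs.append(ts.map(imf))
        resid = resid - imf
        # stop when the residual is monotone (no further oscillation)
        if _strict_peak_indices(resid).size + _strict_peak_indices(-resid).size < 3:
            break
    return imfs, ts.map(resid)


def instantaneous_energy(ts: TimeSeries) -> TimeSeries:
    """Squared analytic-signal magnitude of the mean-removed series (units²)."""
    if len(ts) < 16:
        raise InvalidInputError("instantaneous_energy requires length >= 16")
    resid = ts.values - ts.values.mean()
    return ts.map(np.abs(sps.hilbert(resid)) ** 2)
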