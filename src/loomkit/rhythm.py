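"""Stimulus-locking analysis: detrending, power spectra, cross-correlations.

Darting behavior tends to phase-lock to the 1 Hz repetition cycle of a
looming train, which shows up as a spectral peak at the cycle frequency
and as lag structure in the cross-correlation between running and the
stimulus.  The spectrum here follows a fixed four-step single-sided
construction on the detrended stimulus-window speed trace:

1. ``Y = fft(x)``, ``P2 = |Y| / L`` (two-sided magnitude, L = trace length)
2. keep bins ``0 .. floor(L/2)`` (single-sided)
3. double the interior bins (all but DC and, for even L, Nyquist)
4. square, giving mean-squared amplitude per frequency.

For a pure sinusoid of amplitude A on an exact frequency bin the interior
bin value is A².

Cross-correlations are coefficient-normalised (a signal's autocorrelation
at lag 0 equals 1), matching conventions that report r values in [−1, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as _signal

from .arena import StimulusSchedule
from .events import RunningBout

__all__ = [
    "PowerSpectrum",
    "StimulusIndicator",
    "detrend_linear",
    "power_spectrum",
    "xcorr",
    "xcorr_speed_vs_sine",
    "xcorr_bouts_vs_onsets",
    "bout_matrix",
    "peak_frequency",
    "mean_spectrum",
    "stimulus_indicator",
]


@dataclass
class PowerSpectrum:
    """Single-sided mean-squared-amplitude spectrum."""

    freqs_hz: np.ndarray
    power: np.ndarray
    L: int
    source: str = ""

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"freq_hz": self.freqs_hz, "power": self.power})


@dataclass
class StimulusIndicator:
    """Stimulus reference signals on a uniform time grid.

    ``onset_vector`` is 1 at the sample nearest each repetition onset;
    ``sinusoid`` is sin(2π f (t − train onset)) with f the cycle rate.
    """

    times: np.ndarray
    onset_vector: np.ndarray
    sinusoid: np.ndarray
    rate_hz: float


def detrend_linear(values: np.ndarray) -> np.ndarray:
    """Subtract the least-squares straight line from the data."""
    values = np.asarray(values, dtype=float)
    if values.ndim != 1:
        raise ValueError("expected a 1-D trace")
    return _signal.detrend(values, type="linear")


def power_spectrum(values: np.ndarray, rate_hz: float, source: str = "") -> PowerSpectrum:
    """Single-sided mean-squared-amplitude spectrum of a (detrended) trace.

    The input is used as given — call :func:`detrend_linear` first when
    analysing stimulus-window speed traces.  For odd L there is no Nyquist
    bin, so every bin except DC is doubled.
    """
    x = np.asarray(values, dtype=float)
    L = len(x)
    if L < 4:
        raise ValueError("trace too short for a spectrum (L >= 4 required)")
    Y = np.fft.fft(x)
    P2 = np.abs(Y) / L
    half = L // 2 + 1
    P1 = P2[:half].copy()
    if L % 2 == 0:
        P1[1:-1] *= 2.0
    else:
        P1[1:] *= 2.0
    freqs = np.arange(half) * rate_hz / L
    return PowerSpectrum(freqs_hz=freqs, power=P1**2, L=L, source=source)


def xcorr(x: np.ndarray, y: np.ndarray, rate_hz: float) -> tuple[np.ndarray, np.ndarray]:
    """Coefficient-normalised cross-correlation at all lags.

    Returns ``(lags_s, r)`` with ``r[k] = Σ_n x[n + k] y[n] /
    sqrt(Σ x² Σ y²)``; a positive lag means x is shifted later relative
    to y.  If either signal is identically zero the correlogram is zero.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("signals must share a length")
    c = _signal.correlate(x, y, mode="full")
    lags = _signal.correlation_lags(len(x), len(y), mode="full") / rate_hz
    norm = np.sqrt(np.sum(x**2) * np.sum(y**2))
    r = c / norm if norm > 0 else np.zeros_like(c)
    return lags, r


def stimulus_indicator(
    schedule: StimulusSchedule, rate_hz: float, duration_s: float | None = None
) -> StimulusIndicator:
    """Build onset-vector and sinusoid references over the stimulus window."""
    if duration_s is None:
        duration_s = schedule.duration_s
    n = int(round(duration_s * rate_hz))
    t = schedule.onset_s + np.arange(n) / rate_hz
    onset_vec = np.zeros(n)
    for o in schedule.onsets_s:
        idx = int(round((o - schedule.onset_s) * rate_hz))
        if 0 <= idx < n:
            onset_vec[idx] = 1.0
    f = 1.0 / schedule.cycle_s
    sinusoid = np.sin(2 * np.pi * f * (t - schedule.onset_s))
    return StimulusIndicator(times=t, onset_vector=onset_vec, sinusoid=sinusoid, rate_hz=rate_hz)


def xcorr_speed_vs_sine(
    speed_values: np.ndarray, indicator: StimulusIndicator
) -> tuple[np.ndarray, np.ndarray]:
    """Cross-correlate a (median) speed trace with the stimulus sinusoid."""
    return xcorr(np.asarray(speed_values, float), indicator.sinusoid, indicator.rate_hz)


def bout_matrix(
    bout_lists: list[list[RunningBout]], indicator: StimulusIndicator
) -> np.ndarray:
    """Binary per-trial rows: 1 where a running bout is in progress."""
    t = indicator.times
    M = np.zeros((len(bout_lists), len(t)))
    for i, bouts in enumerate(bout_lists):
        for b in bouts:
            M[i, (t >= b.start_s - 1e-9) & (t < b.end_s - 1e-9)] = 1.0
    return M


def xcorr_bouts_vs_onsets(
    bout_mat: np.ndarray, indicator: StimulusIndicator
) -> tuple[np.ndarray, np.ndarray]:
    """Mean of per-trial normalised cross-correlations with the onset vector.

    Each row of ``bout_mat`` is correlated with the onset vector
    (coefficient normalisation); rows with no bouts contribute a zero
    correlogram.  The mean across rows is returned.
    """
    bout_mat = np.atleast_2d(np.asarray(bout_mat, dtype=float))
    rows = []
    lags = None
    for row in bout_mat:
        lags, r = xcorr(row, indicator.onset_vector, indicator.rate_hz)
        rows.append(r)
    return lags, np.mean(rows, axis=0)


def peak_frequency(spec: PowerSpectrum, band_hz: tuple[float, float]) -> float:
    """Frequency of maximal power within ``band_hz`` (ties -> lower frequency)."""
    lo, hi = band_hz
    mask = (spec.freqs_hz >= lo) & (spec.freqs_hz <= hi)
    if not mask.any():
        raise ValueError("band contains no frequency bins")
    freqs = spec.freqs_hz[mask]
    power = spec.power[mask]
    return float(freqs[int(np.argmax(power))])


def mean_spectrum(spectra: list[PowerSpectrum]) -> PowerSpectrum:
    """Average spectra computed on equal-length traces."""
    if not spectra:
        raise ValueError("no spectra to average")
    L = spectra[0].L
    if any(s.L != L for s in spectra):
        raise ValueError("spectra must share the trace length")
    return PowerSpectrum(
        freqs_hz=spectra[0].freqs_hz,
        power=np.mean([s.power for s in spectra], axis=0),
        L=L,
        source="mean",
    )
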