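"""Event-triggered time-frequency maps and multi-taper spectra.

Used to verify ripple abolition: spectra are computed in 150 ms windows
around detected events, and baseline-normalised by subtracting spectra
taken 400 ms away from each event.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.signal import windows


@dataclass
class TimeFrequencyMap:
    """Average power around events; ``power`` has shape (n_freqs, n_offsets)."""

    offsets: np.ndarray      # window-centre times relative to the event, s
    frequencies: np.ndarray
    power: np.ndarray
    window_length: float
    n_events: int

    def slice_at(self, offset: float) -> np.ndarray:
        """Power spectrum of the time slice nearest ``offset``."""
        i = int(np.argmin(np.abs(self.offsets - offset)))
        return self.power[:, i]


@dataclass
class NormalizedSpectrum:
    """Event spectrum minus shifted-baseline spectrum (may be negative)."""

    frequencies: np.ndarray
    power_difference: np.ndarray
    n_events: int
    shift: float


@lru_cache(maxsize=32)
def _dpss_tapers(n: int, nw: float, n_tapers: int) -> np.ndarray:
    return windows.dpss(n, nw, n_tapers)


def multitaper_spectrum(
    segment: np.ndarray,
    fs: float,
    nw: float = 3.0,
    n_tapers: int = 5,
) -> tuple[np.ndarray, np.ndarray]:
    """Slepian-taper averaged periodogram of one segment.

    Returns (frequencies, power). With unit-norm tapers the power sums
    (times the frequency step) to approximately the segment variance.
    """
    x = np.asarray(segment, dtype=float)
    n = len(x)
    if n < 8:
        raise ValueError("segment too short for a spectral estimate")
    if n_tapers > int(2 * nw) - 1:
        raise ValueError("n_tapers must not exceed 2*NW - 1")
    tapers = _dpss_tapers(n, nw, n_tapers)
    # remove the mean so DC leakage does not mask low frequencies
    x = x - x.mean()
    spec = np.abs(np.fft.rfft(tapers * x[None, :], axis=1)) ** 2
    power = spec.mean(axis=0) / fs
    # one-sided: double everything except DC (and Nyquist when n is even)
    if n % 2 == 0:
        power[1:-1] *= 2
    else:
        power[1:] *= 2
    freqs = np.fft.rfftfreq(n, 1 / fs)
    return freqs, power


def _event_windows(
    signal_len: int,
    fs: float,
    event_times: np.ndarray,
    centers: np.ndarray,
    n_win: int,
) -> np.ndarray:
    """Start indices (n_events, n_centers) for in-bounds events; drops
    events whose tiling would run off either end."""
    ev = np.asarray(event_times, dtype=float)
    starts = np.rint((ev[:, None] + centers[None, :]) * fs).astype(int) - n_win // 2
    ok = (starts.min(axis=1) >= 0) & (starts.max(axis=1) + n_win <= signal_len)
    return starts[ok]


def triggered_spectrogram(
    x: np.ndarray,
    fs: float,
    event_times: np.ndarray,
    window: float = 0.150,
    span: float = 1.0,
    overlap: float = 0.75,
    align_shift: float = 0.0,
    nw: float = 3.0,
    n_tapers: int = 5,
) -> TimeFrequencyMap:
    """Average multi-taper power in sliding windows around each event.

    ``align_shift`` subtracts a constant from the event times before
    alignment; passing the control-mode laser delay makes the triggering
    SWR event appear at time 0 even when ``event_times`` are laser onsets.
    """
    ev = np.asarray(event_times, dtype=float) - align_shift
    n_win = int(round(window * fs))
    step = window * (1 - overlap)
    centers = np.arange(-span, span + step / 2, step)
    starts = _event_windows(len(x), fs, ev, centers, n_win)
    if starts.shape[0] == 0:
        raise ValueError("no events with a full analysis span inside the signal")
    x = np.asarray(x, dtype=float)
    n_freqs = n_win // 2 + 1
    power = np.zeros((n_freqs, len(centers)))
    for row in starts:
        for j, s in enumerate(row):
            _, p = multitaper_spectrum(x[s:s + n_win], fs, nw, n_tapers)
            power[:, j] += p
    power /= starts.shape[0]
    freqs = np.fft.rfftfreq(n_win, 1 / fs)
    return TimeFrequencyMap(centers, freqs, power, window, starts.shape[0])


def normalized_event_spectrum(
    x: np.ndarray,
    fs: float,
    event_times: np.ndarray,
    shift: float = 0.400,
    window: float = 0.150,
    nw: float = 3.0,
    n_tapers: int = 5,
) -> NormalizedSpectrum:
    """Mean multi-taper spectrum at events minus the mean at events shifted
    by ``shift`` seconds; removes the stationary background spectrum."""
    x = np.asarray(x, dtype=float)
    ev = np.asarray(event_times, dtype=float)
    n_win = int(round(window * fs))
    half = n_win // 2
    starts_ev = np.rint(ev * fs).astype(int) - half
    starts_bl = np.rint((ev + shift) * fs).astype(int) - half
    ok = (np.minimum(starts_ev, starts_bl) >= 0) & (
        np.maximum(starts_ev, starts_bl) + n_win <= len(x))
    if not ok.any():
        raise ValueError("no events with both windows inside the signal")
    acc_ev = np.zeros(n_win // 2 + 1)
    acc_bl = np.zeros_like(acc_ev)
    for se, sb in zip(starts_ev[ok], starts_bl[ok]):
        _, pe = multitaper_spectrum(x[se:se + n_win], fs, nw, n_tapers)
        _, pb = multitaper_spectrum(x[sb:sb + n_win], fs, nw, n_tapers)
        acc_ev += pe
        acc_bl += pb
    n_used = int(ok.sum())
    freqs = np.fft.rfftfreq(n_win, 1 / fs)
    return NormalizedSpectrum(freqs, (acc_ev - acc_bl) / n_used, n_used, shift)


def peak_frequency(
    frequencies: np.ndarray,
    power: np.ndarray,
    band: tuple[float, float] = (100.0, 250.0),
) -> float:
    """Frequency of maximal power within ``band`` (inclusive)."""
    f = np.asarray(frequencies, dtype=float)
    p = np.asarray(power, dtype=float)
    mask = (f >= band[0]) & (f <= band[1])
    if not mask.any():
        raise ValueError("band contains no frequency bins")
    return float(f[mask][np.argmax(p[mask])])
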