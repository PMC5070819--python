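"""Closed-loop ripple detector emulation and offline detection.

The online path digitally emulates the analog detector used in vivo: the
pyramidal-layer minus radiatum differential signal is band-pass filtered by
a causal 4-pole filter centred near 150 Hz, amplified, and compared against
a threshold; each upward crossing outside an active pulse emits a 200 ms
TTL. In the delayed control mode the laser pulses are the TTLs shifted by a
fixed delay (1.32 s by default) so they miss the triggering event while
delivering identical light energy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .core import (
    ChannelRole,
    EventProvenance,
    LfpRecording,
    PulseMode,
    PulseTrain,
    RippleEventTable,
)


@dataclass(frozen=True)
class DetectorConfig:
    """Parameters of the emulated analog ripple detector.

    ``band`` brackets ``center_freq``; ``filter_order`` counts analog poles
    (a band-pass Butterworth of order N has 2N poles, so 4 poles = order-2
    design). ``threshold_sd`` is in multiples of the filtered signal's SD.
    """

    center_freq: float = 150.0
    band: tuple[float, float] = (100.0, 200.0)
    filter_order: int = 4
    gain: float = 10.0
    threshold_sd: float = 4.0
    pulse_length: float = 0.200
    control_delay: float = 1.32

    def __post_init__(self) -> None:
        if self.pulse_length <= 0:
            raise ValueError("pulse length must be positive")
        if self.control_delay < 0:
            raise ValueError("control delay must be non-negative")
        if self.filter_order < 2 or self.filter_order % 2:
            raise ValueError("filter_order counts poles and must be even >= 2")
        if not self.band[0] < self.center_freq < self.band[1]:
            raise ValueError("band must bracket the center frequency")


@dataclass(frozen=True)
class OfflineDetectorParams:
    """Non-stringent offline detector: low threshold so truncated,
    low-amplitude event remnants are still found."""

    band: tuple[float, float] = (100.0, 250.0)
    threshold_sd: float = 2.0
    min_duration: float = 0.015
    max_duration: float = 0.500
    merge_gap: float = 0.010
    smooth_window: float = 0.010


@dataclass
class DetectionEvaluation:
    """Match statistics between a detected table and ground truth."""

    precision: float
    recall: float
    n_detected: int
    n_truth: int
    n_matched: int
    latencies: np.ndarray            # matched detected onset - truth onset, s
    latency_cycles: np.ndarray       # same, in ripple cycles

    @property
    def mean_latency(self) -> float:
        return float(np.mean(self.latencies)) if len(self.latencies) else float("nan")


def differential_signal(lfp: LfpRecording) -> np.ndarray:
    """Pyramidale minus radiatum channel; isolates the ripple oscillation
    while cancelling common-mode noise."""
    return lfp.channel(ChannelRole.PYRAMIDALE) - lfp.channel(ChannelRole.RADIATUM)


def _design_sos(config: DetectorConfig, fs: float) -> np.ndarray:
    lo, hi = config.band
    if hi >= fs / 2:
        raise ValueError("band edge at or above Nyquist frequency")
    order = config.filter_order // 2
    return signal.butter(order, [lo, hi], btype="bandpass", fs=fs, output="sos")


def ripple_bandpass(x: np.ndarray, fs: float, config: DetectorConfig = DetectorConfig()) -> np.ndarray:
    """Causal band-pass plus gain, emulating the analog filter stage."""
    sos = _design_sos(config, fs)
    return config.gain * signal.sosfilt(sos, np.asarray(x, dtype=float))


def online_closed_loop(
    filtered: np.ndarray,
    fs: float,
    config: DetectorConfig = DetectorConfig(),
    mode: PulseMode | str = PulseMode.DIRECT,
    threshold: float | None = None,
) -> tuple[PulseTrain, PulseTrain]:
    """Causal threshold scan of the filtered signal.

    Emits a TTL of ``pulse_length`` at each upward crossing of the rectified
    signal outside an active TTL; no TTL can begin while one is running.
    Returns (ttl, laser): in direct mode the laser pulses coincide with the
    TTLs, in delayed mode they are shifted by ``control_delay``.

    ``threshold`` is absolute (post-gain); if None it is ``threshold_sd``
    times the SD of the filtered signal.
    """
    mode = PulseMode(mode)
    x = np.abs(np.asarray(filtered, dtype=float))
    if threshold is None:
        threshold = config.threshold_sd * float(np.std(filtered))
    if threshold <= 0:
        raise ValueError("threshold must be positive")

    above = np.flatnonzero(x >= threshold)
    pulse_samples = int(round(config.pulse_length * fs))
    onsets: list[int] = []
    next_free = -1
    for i in above:
        if i >= next_free:
            onsets.append(i)
            next_free = i + pulse_samples
    ttl = PulseTrain(np.asarray(onsets, dtype=float) / fs, config.pulse_length,
                     mode=PulseMode.DIRECT)
    if mode is PulseMode.DIRECT:
        laser = PulseTrain(ttl.onsets.copy(), config.pulse_length, mode=PulseMode.DIRECT)
    else:
        laser = ttl.shifted(config.control_delay)
    return ttl, laser


def offline_detect(
    lfp: LfpRecording,
    params: OfflineDetectorParams = OfflineDetectorParams(),
) -> RippleEventTable:
    """Non-stringent offline SWR detection on the differential signal.

    Band-pass (zero-phase) -> rectify -> moving-average envelope -> z-score
    against session statistics -> contiguous suprathreshold runs within the
    duration bounds become events; runs closer than ``merge_gap`` merge.
    """
    fs = lfp.sampling_rate
    x = differential_signal(lfp)
    if len(x) == 0:
        return RippleEventTable.from_arrays([], [], provenance=EventProvenance.OFFLINE)
    sos = signal.butter(2, list(params.band), btype="bandpass", fs=fs, output="sos")
    bp = signal.sosfiltfilt(sos, x)
    win = max(1, int(round(params.smooth_window * fs)))
    env = np.convolve(np.abs(bp), np.ones(win) / win, mode="same")
    mu, sd = env.mean(), env.std()
    if sd == 0:
        return RippleEventTable.from_arrays([], [], provenance=EventProvenance.OFFLINE)
    z = (env - mu) / sd

    above = z >= params.threshold_sd
    if not above.any():
        return RippleEventTable.from_arrays([], [], provenance=EventProvenance.OFFLINE)
    edges = np.diff(above.astype(int))
    starts = np.flatnonzero(edges == 1) + 1
    ends = np.flatnonzero(edges == -1) + 1
    if above[0]:
        starts = np.concatenate([[0], starts])
    if above[-1]:
        ends = np.concatenate([ends, [len(above)]])

    # merge runs separated by less than merge_gap
    gap = int(round(params.merge_gap * fs))
    merged: list[list[int]] = []
    for s, e in zip(starts, ends):
        if merged and s - merged[-1][1] <= gap:
            merged[-1][1] = e
        else:
            merged.append([s, int(e)])

    rows = {"onset": [], "offset": [], "peak_time": [], "peak_frequency": [],
            "amplitude": []}
    min_n = int(round(params.min_duration * fs))
    max_n = int(round(params.max_duration * fs))
    for s, e in merged:
        if not (min_n <= e - s <= max_n):
            continue
        seg = bp[s:e]
        peak_i = s + int(np.argmax(env[s:e]))
        nfft = max(len(seg), int(fs / 4))  # >=4 Hz resolution
        spec = np.abs(np.fft.rfft(seg, nfft)) ** 2
        freqs = np.fft.rfftfreq(nfft, 1 / fs)
        inband = (freqs >= params.band[0]) & (freqs <= params.band[1])
        pf = float(freqs[inband][np.argmax(spec[inband])]) if inband.any() else np.nan
        rows["onset"].append(s / fs)
        rows["offset"].append(e / fs)
        rows["peak_time"].append(peak_i / fs)
        rows["peak_frequency"].append(pf)
        rows["amplitude"].append(float(z[peak_i]))
    return RippleEventTable.from_arrays(
        rows["onset"], rows["offset"], rows["peak_time"], rows["peak_frequency"],
        rows["amplitude"], provenance=EventProvenance.OFFLINE)


def evaluate_detection(
    detected: RippleEventTable | PulseTrain,
    truth: RippleEventTable,
    tolerance: float = 0.05,
    ripple_freq: float = 160.0,
) -> DetectionEvaluation:
    """Greedy one-to-one matching of detected onsets to ground-truth events.

    A detected onset matches a truth event if it falls within
    [truth.onset - tolerance, truth.offset + tolerance]; each truth event
    takes the earliest unmatched detection. Latency is detected onset minus
    truth onset (clipped at zero: a detection inside the event but before
    the envelope peak cannot be "negative" relative to the event start).
    """
    det_onsets = detected.onsets if isinstance(detected, (RippleEventTable, PulseTrain)) else np.asarray(detected)
    det_onsets = np.sort(np.asarray(det_onsets, dtype=float))
    n_det, n_tru = len(det_onsets), len(truth)
    used = np.zeros(n_det, dtype=bool)
    latencies = []
    for onset, offset in zip(truth.onsets, truth.offsets):
        lo, hi = onset - tolerance, offset + tolerance
        idx = np.flatnonzero((det_onsets >= lo) & (det_onsets <= hi) & ~used)
        if len(idx):
            j = idx[0]
            used[j] = True
            latencies.append(max(det_onsets[j] - onset, 0.0))
    lat = np.asarray(latencies)
    n_matched = len(lat)
    precision = n_matched / n_det if n_det else float("nan")
    recall = n_matched / n_tru if n_tru else float("nan")
    return DetectionEvaluation(
        precision=precision, recall=recall, n_detected=n_det, n_truth=n_tru,
        n_matched=n_matched, latencies=lat, latency_cycles=lat * ripple_freq)
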