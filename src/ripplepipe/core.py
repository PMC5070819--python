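"""Domain containers shared across the pipeline.

Conventions: all times are seconds from the start of the recording day,
positions are centimetres, LFP samples are signed 16-bit integers with a
``scale`` factor giving volts per unit. Conversion between seconds and
sample indices happens only at I/O and detection boundaries.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd


class ArenaShape(str, enum.Enum):
    RECTANGLE = "rectangle"
    CIRCLE = "circle"


class UnitClass(str, enum.Enum):
    PYRAMIDAL = "pyramidal"
    INTERNEURON = "interneuron"


class ChannelRole(str, enum.Enum):
    PYRAMIDALE = "pyramidale"
    RADIATUM = "radiatum"
    OTHER = "other"


class PulseMode(str, enum.Enum):
    DIRECT = "direct"
    DELAYED = "delayed"


class PulseIntensity(str, enum.Enum):
    FULL = "full"
    HALF = "half"


class EventProvenance(str, enum.Enum):
    GROUND_TRUTH = "ground_truth"
    ONLINE = "online"
    OFFLINE = "offline"


@dataclass(frozen=True)
class Arena:
    """Enclosure geometry. ``dimensions`` is (width, height) for a rectangle
    and (diameter,) for a circle; the coordinate origin is the arena centre."""

    shape: ArenaShape
    dimensions: tuple[float, ...]

    def __post_init__(self) -> None:
        shape = ArenaShape(self.shape)
        object.__setattr__(self, "shape", shape)
        dims = tuple(float(d) for d in self.dimensions)
        object.__setattr__(self, "dimensions", dims)
        if any(d <= 0 for d in dims):
            raise ValueError("arena dimensions must be positive")
        n_expected = 2 if shape is ArenaShape.RECTANGLE else 1
        if len(dims) != n_expected:
            raise ValueError(
                f"{shape.value} arena needs {n_expected} dimension(s), got {len(dims)}"
            )

    @property
    def extent(self) -> tuple[float, float]:
        """(width, height) of the bounding box, centred on the origin."""
        if self.shape is ArenaShape.RECTANGLE:
            return self.dimensions  # type: ignore[return-value]
        d = self.dimensions[0]
        return (d, d)

    def contains(self, positions: np.ndarray, tol: float = 1e-9) -> np.ndarray:
        """Boolean mask of points inside the arena (positions shape (n, 2))."""
        pos = np.atleast_2d(np.asarray(positions, dtype=float))
        if self.shape is ArenaShape.RECTANGLE:
            w, h = self.dimensions
            return (
                (np.abs(pos[:, 0]) <= w / 2 + tol)
                & (np.abs(pos[:, 1]) <= h / 2 + tol)
            )
        r = self.dimensions[0] / 2
        return np.hypot(pos[:, 0], pos[:, 1]) <= r + tol


@dataclass
class Trajectory:
    """Uniformly sampled 2-D position track."""

    times: np.ndarray
    positions: np.ndarray
    arena: Arena

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 2)
        if len(self.times) != len(self.positions):
            raise ValueError("times and positions must have equal length")
        if len(self.times) > 1:
            dt = np.diff(self.times)
            if np.any(dt <= 0):
                raise ValueError("trajectory times must be strictly increasing")
        if len(self.positions) and not self.arena.contains(self.positions).all():
            raise ValueError("trajectory positions must lie inside the arena")

    def __len__(self) -> int:
        return len(self.times)

    @property
    def step(self) -> float:
        if len(self.times) < 2:
            return float("nan")
        return float(np.median(np.diff(self.times)))

    @property
    def duration(self) -> float:
        return 0.0 if len(self.times) < 2 else float(self.times[-1] - self.times[0])

    @property
    def speeds(self) -> np.ndarray:
        """Instantaneous speed (cm/s), same length as ``times``."""
        n = len(self.times)
        if n < 2:
            return np.zeros(n)
        d = np.linalg.norm(np.diff(self.positions, axis=0), axis=1)
        v = d / np.diff(self.times)
        # attribute the first step's speed to the first sample
        return np.concatenate([[v[0]], v])

    def position_at(self, t: np.ndarray) -> np.ndarray:
        """Linearly interpolated position at arbitrary times."""
        t = np.asarray(t, dtype=float)
        x = np.interp(t, self.times, self.positions[:, 0])
        y = np.interp(t, self.times, self.positions[:, 1])
        return np.column_stack([x, y])

    def speed_at(self, t: np.ndarray) -> np.ndarray:
        return np.interp(np.asarray(t, dtype=float), self.times, self.speeds)


@dataclass
class PlaceFieldModel:
    """Single-Gaussian place field: lambda(x) = baseline + peak * exp(-|x-c|^2 / 2 sigma^2)."""

    center: tuple[float, float]
    width: float
    peak_rate: float
    baseline_rate: float = 0.0

    def __post_init__(self) -> None:
        self.center = (float(self.center[0]), float(self.center[1]))
        if self.width <= 0:
            raise ValueError("place-field width must be positive")
        if self.baseline_rate < 0:
            raise ValueError("baseline rate must be non-negative")
        if self.peak_rate < 0:
            raise ValueError("peak rate must be non-negative")

    def rate(self, positions: np.ndarray) -> np.ndarray:
        pos = np.atleast_2d(np.asarray(positions, dtype=float))
        d2 = (pos[:, 0] - self.center[0]) ** 2 + (pos[:, 1] - self.center[1]) ** 2
        return self.baseline_rate + self.peak_rate * np.exp(-d2 / (2 * self.width**2))


@dataclass
class PlaceFieldEnsemble:
    """Per-cell place-field models for exploration 1 and 2 of the same arena."""

    arena: Arena
    session1: list[PlaceFieldModel]
    session2: list[PlaceFieldModel]

    def __post_init__(self) -> None:
        if len(self.session1) != len(self.session2):
            raise ValueError("both sessions must model the same cells")

    @property
    def n_cells(self) -> int:
        return len(self.session1)

    def drifts(self) -> np.ndarray:
        """Per-cell field-centre displacement (cm) between the two sessions."""
        c1 = np.array([m.center for m in self.session1])
        c2 = np.array([m.center for m in self.session2])
        return np.linalg.norm(c2 - c1, axis=1)


@dataclass
class SpikeTrainSet:
    """Sorted spike times per unit."""

    trains: dict[int, np.ndarray]
    unit_classes: dict[int, UnitClass] = field(default_factory=dict)
    session: str = ""

    def __post_init__(self) -> None:
        clean: dict[int, np.ndarray] = {}
        for uid, t in self.trains.items():
            t = np.sort(np.asarray(t, dtype=float))
            if len(t) and t[0] < 0:
                raise ValueError(f"unit {uid} has negative spike times")
            clean[int(uid)] = t
        self.trains = clean
        self.unit_classes = {
            int(u): UnitClass(c) for u, c in self.unit_classes.items()
        }

    @property
    def unit_ids(self) -> list[int]:
        return sorted(self.trains)

    @property
    def n_units(self) -> int:
        return len(self.trains)

    def n_spikes(self) -> int:
        return int(sum(len(t) for t in self.trains.values()))

    def restrict(self, start: float, end: float, session: str | None = None) -> "SpikeTrainSet":
        """Spikes with start <= t < end, times kept on the day clock."""
        trains = {
            uid: t[(t >= start) & (t < end)] for uid, t in self.trains.items()
        }
        return SpikeTrainSet(trains, dict(self.unit_classes),
                             self.session if session is None else session)


@dataclass
class LfpRecording:
    """Multi-channel continuous recording; ``samples`` shape (n_channels, n)."""

    samples: np.ndarray
    sampling_rate: float
    channel_roles: list[ChannelRole]
    scale: float = 1e-6  # volts per int16 unit

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples))
        if self.samples.dtype != np.int16:
            self.samples = np.clip(np.rint(self.samples), -32768, 32767).astype(np.int16)
        if self.sampling_rate <= 0:
            raise ValueError("sampling rate must be positive")
        self.channel_roles = [ChannelRole(r) for r in self.channel_roles]
        if len(self.channel_roles) != self.samples.shape[0]:
            raise ValueError("one role per channel required")

    @property
    def n_channels(self) -> int:
        return int(self.samples.shape[0])

    @property
    def n_samples(self) -> int:
        return int(self.samples.shape[1])

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate

    def channel(self, role: ChannelRole | str) -> np.ndarray:
        """The unique channel tagged with ``role`` as float array."""
        role = ChannelRole(role)
        idx = [i for i, r in enumerate(self.channel_roles) if r == role]
        if len(idx) != 1:
            raise ValueError(
                f"expected exactly one {role.value} channel, found {len(idx)}"
            )
        return self.samples[idx[0]].astype(float)


_EVENT_COLUMNS = ["onset", "offset", "peak_time", "peak_frequency", "amplitude"]


@dataclass
class RippleEventTable:
    """Detected or ground-truth ripple events, sorted and non-overlapping."""

    events: pd.DataFrame
    provenance: EventProvenance = EventProvenance.OFFLINE

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.events)
        for col in _EVENT_COLUMNS:
            if col not in df.columns:
                df[col] = np.nan
        df = df[_EVENT_COLUMNS].astype(float).sort_values("onset").reset_index(drop=True)
        if len(df):
            if not (df["onset"] < df["offset"]).all():
                raise ValueError("event onsets must precede offsets")
            if (df["onset"].values[1:] < df["offset"].values[:-1]).any():
                raise ValueError("events must not overlap")
        self.events = df
        self.provenance = EventProvenance(self.provenance)

    @classmethod
    def from_arrays(cls, onset, offset, peak_time=None, peak_frequency=None,
                    amplitude=None, provenance=EventProvenance.OFFLINE) -> "RippleEventTable":
        onset = np.asarray(onset, dtype=float)
        df = pd.DataFrame({
            "onset": onset,
            "offset": np.asarray(offset, dtype=float),
            "peak_time": np.full(len(onset), np.nan) if peak_time is None else peak_time,
            "peak_frequency": np.full(len(onset), np.nan) if peak_frequency is None else peak_frequency,
            "amplitude": np.full(len(onset), np.nan) if amplitude is None else amplitude,
        })
        return cls(df, provenance)

    def __len__(self) -> int:
        return len(self.events)

    @property
    def onsets(self) -> np.ndarray:
        return self.events["onset"].to_numpy()

    @property
    def offsets(self) -> np.ndarray:
        return self.events["offset"].to_numpy()

    @property
    def peak_times(self) -> np.ndarray:
        return self.events["peak_time"].to_numpy()


@dataclass
class PulseTrain:
    """TTL or laser pulses of fixed duration."""

    onsets: np.ndarray
    duration: float
    mode: PulseMode = PulseMode.DIRECT
    intensity: PulseIntensity = PulseIntensity.FULL
    delay: float = 0.0

    def __post_init__(self) -> None:
        self.onsets = np.sort(np.asarray(self.onsets, dtype=float))
        if self.duration <= 0:
            raise ValueError("pulse duration must be positive")
        self.mode = PulseMode(self.mode)
        self.intensity = PulseIntensity(self.intensity)
        if self.mode is PulseMode.DELAYED and self.delay <= 0:
            raise ValueError("delayed mode requires a positive delay")
        if len(self.onsets) > 1 and np.any(np.diff(self.onsets) < self.duration):
            raise ValueError("pulses must not overlap")

    def __len__(self) -> int:
        return len(self.onsets)

    @property
    def offsets(self) -> np.ndarray:
        return self.onsets + self.duration

    @property
    def total_duration(self) -> float:
        return float(len(self.onsets) * self.duration)

    def shifted(self, delay: float) -> "PulseTrain":
        return PulseTrain(self.onsets + delay, self.duration,
                          PulseMode.DELAYED if delay > 0 else self.mode,
                          self.intensity, delay)

    def contains(self, times: np.ndarray) -> np.ndarray:
        """Mask of spike/sample times falling inside any pulse window."""
        t = np.asarray(times, dtype=float)
        if len(self.onsets) == 0:
            return np.zeros(t.shape, dtype=bool)
        idx = np.searchsorted(self.onsets, t, side="right") - 1
        ok = idx >= 0
        inside = np.zeros(t.shape, dtype=bool)
        inside[ok] = t[ok] < self.onsets[idx[ok]] + self.duration
        return inside


@dataclass
class OccupancyMap:
    """Dwell time (s) per square spatial bin."""

    x_edges: np.ndarray
    y_edges: np.ndarray
    dwell: np.ndarray  # shape (nx, ny)
    valid: np.ndarray
    bin_size: float
    speed_threshold: float | None = None

    def __post_init__(self) -> None:
        self.dwell = np.asarray(self.dwell, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.dwell.shape != self.valid.shape:
            raise ValueError("dwell and validity mask shapes differ")
        if np.any(self.dwell < 0):
            raise ValueError("dwell times must be non-negative")

    @property
    def total_dwell(self) -> float:
        return float(self.dwell.sum())

    @property
    def occupancy_fraction(self) -> np.ndarray:
        tot = self.dwell.sum()
        return self.dwell / tot if tot > 0 else np.zeros_like(self.dwell)


@dataclass
class RateMap:
    """Occupancy-normalised firing-rate grid; invalid bins are NaN."""

    rate: np.ndarray          # possibly smoothed (nx, ny), NaN on invalid bins
    rate_unsmoothed: np.ndarray
    valid: np.ndarray
    smoothing_sigma: float    # in bins; 0 = unsmoothed
    bin_size: float

    def __post_init__(self) -> None:
        self.rate = np.asarray(self.rate, dtype=float)
        self.rate_unsmoothed = np.asarray(self.rate_unsmoothed, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        with np.errstate(invalid="ignore"):
            if np.nanmin(np.where(self.valid, self.rate, np.nan), initial=0) < 0:
                raise ValueError("rates must be non-negative on valid bins")

    @property
    def peak_rate(self) -> float:
        vals = self.rate[self.valid]
        return float(np.nanmax(vals)) if vals.size else float("nan")
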