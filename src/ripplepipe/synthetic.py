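"""Synthetic inputs with known ground truth.

Everything the downstream stages consume can be generated here: exploration
trajectories, drifting place-cell ensembles, inhomogeneous-Poisson spike
trains, sleep LFP with injected sharp wave/ripple (SWR) events, and
light-pulse suppression of spiking. All generators are deterministic given
(parameters, seed).

Default magnitudes emulate mouse CA1 recordings: a 60x60 cm novel enclosure
explored at ~8 cm/s, Gaussian place fields of ~5 cm radius with peak rates
of a few Hz to ~12 Hz, sleep SWR events at ~0.3/s carrying a 160 Hz ripple
in the pyramidal-layer channel and a concurrent negative sharp wave in the
radiatum channel.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import signal

from .core import (
    Arena,
    ArenaShape,
    ChannelRole,
    EventProvenance,
    LfpRecording,
    PlaceFieldEnsemble,
    PlaceFieldModel,
    PulseTrain,
    RippleEventTable,
    SpikeTrainSet,
    Trajectory,
    UnitClass,
)

DEFAULT_ARENA = Arena(ArenaShape.RECTANGLE, (60.0, 60.0))


@dataclass(frozen=True)
class SpeedParams:
    """Mean-reverting (Ornstein-Uhlenbeck) velocity parameters.

    mean_speed sets the stationary Rayleigh speed scale, tau the velocity
    autocorrelation time, max_speed a hard cap (cm/s).
    """

    mean_speed: float = 8.0
    tau: float = 0.7
    max_speed: float = 30.0


@dataclass(frozen=True)
class StabilityParams:
    """Between-session change of the place-field models.

    ``drift`` is the mean field-centre displacement in cm (may be an array
    with one entry per cell for mixed populations), ``drift_sd`` its per-cell
    spread; ``rate_scale`` multiplies session-2 peak rates.
    """

    drift: float | Sequence[float] = 0.0
    drift_sd: float = 0.0
    rate_scale: float = 1.0
    rate_scale_sd: float = 0.0


@dataclass(frozen=True)
class NoiseParams:
    """Background LFP noise: 1/f^(exponent/2) amplitude shaping, target SD in
    int16 units."""

    sd: float = 200.0
    exponent: float = 1.0


@dataclass(frozen=True)
class ReboundParams:
    """Post-pulse rebound spiking: extra Poisson spikes in ``window`` seconds
    after each pulse offset at ``rate_factor`` times the unit's mean rate."""

    window: float = 0.05
    rate_factor: float = 2.0


def simulate_trajectory(
    arena: Arena,
    duration: float,
    step: float = 0.025,
    speed_params: SpeedParams = SpeedParams(),
    seed: int | np.random.Generator = 0,
) -> Trajectory:
    """Smooth random exploration of the arena.

    The velocity follows a mean-reverting Gaussian process and walls are
    reflective, producing a space-filling walk whose stationary speeds are
    approximately Rayleigh with mean ``speed_params.mean_speed``.
    """
    if duration < 0 or step <= 0:
        raise ValueError("duration must be >= 0 and step > 0")
    rng = np.random.default_rng(seed)
    n = int(round(duration / step))
    times = np.arange(n) * step
    if n == 0:
        return Trajectory(times, np.zeros((0, 2)), arena)

    sp = speed_params
    if sp.max_speed == 0 or sp.mean_speed == 0:
        pos = np.zeros((n, 2))
        return Trajectory(times, pos, arena)

    # stationary 2-D OU speed is Rayleigh(sigma_s); mean = sigma_s*sqrt(pi/2)
    sigma_s = sp.mean_speed / np.sqrt(np.pi / 2)
    sigma_v = sigma_s * np.sqrt(2.0 / sp.tau)
    decay = np.exp(-step / sp.tau)
    kick = sigma_v * np.sqrt((1 - decay**2) * sp.tau / 2)

    w, h = arena.extent
    pos = np.empty((n, 2))
    p = np.zeros(2)
    v = rng.normal(0, sigma_s, 2)
    noise = rng.normal(0, kick, (n, 2))
    radius = arena.dimensions[0] / 2 if arena.shape is ArenaShape.CIRCLE else None
    for i in range(n):
        v = v * decay + noise[i]
        speed = np.hypot(*v)
        if speed > sp.max_speed:
            v *= sp.max_speed / speed
        p = p + v * step
        if radius is None:
            for k, half in enumerate((w / 2, h / 2)):
                if p[k] > half:
                    p[k] = 2 * half - p[k]
                    v[k] = -v[k]
                elif p[k] < -half:
                    p[k] = -2 * half - p[k]
                    v[k] = -v[k]
        else:
            r = np.hypot(*p)
            if r > radius:
                # mirror across the circular wall, reflect radial velocity
                normal = p / r
                p = p - 2 * (r - radius) * normal
                v = v - 2 * np.dot(v, normal) * normal
        pos[i] = p
    # numerical safety against corner double-reflections
    if radius is None:
        pos[:, 0] = np.clip(pos[:, 0], -w / 2, w / 2)
        pos[:, 1] = np.clip(pos[:, 1], -h / 2, h / 2)
    else:
        r = np.hypot(pos[:, 0], pos[:, 1])
        over = r > radius
        pos[over] *= (radius / r[over])[:, None]
    return Trajectory(times, pos, arena)


def make_ensemble(
    n_cells: int,
    arena: Arena = DEFAULT_ARENA,
    stability_params: StabilityParams = StabilityParams(),
    seed: int | np.random.Generator = 0,
    field_width: float = 5.0,
    peak_rate_range: tuple[float, float] = (4.0, 12.0),
    baseline_rate: float = 0.1,
) -> PlaceFieldEnsemble:
    """Draw a place-cell ensemble for exploration 1 and its (possibly
    drifted and rate-scaled) counterpart for exploration 2."""
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    sp = stability_params
    drift = np.broadcast_to(np.asarray(sp.drift, dtype=float), (n_cells,))
    max_extent = float(max(arena.extent))
    if np.any(drift > max_extent):
        raise ValueError("drift cannot exceed the arena extent")
    rng = np.random.default_rng(seed)

    w, h = arena.extent
    margin = field_width
    centers = np.empty((n_cells, 2))
    filled = 0
    while filled < n_cells:  # rejection keeps circular-arena centres inside
        cand = rng.uniform([-w / 2 + margin, -h / 2 + margin],
                           [w / 2 - margin, h / 2 - margin], (n_cells - filled, 2))
        ok = arena.contains(cand)
        k = int(ok.sum())
        centers[filled:filled + k] = cand[ok]
        filled += k
    peaks = rng.uniform(*peak_rate_range, n_cells)

    session1 = [
        PlaceFieldModel(tuple(c), field_width, pk, baseline_rate)
        for c, pk in zip(centers, peaks)
    ]

    mags = np.abs(drift + rng.normal(0, sp.drift_sd, n_cells)) if sp.drift_sd > 0 else drift.copy()
    scales = np.clip(rng.normal(sp.rate_scale, sp.rate_scale_sd, n_cells), 0.05, None) \
        if sp.rate_scale_sd > 0 else np.full(n_cells, sp.rate_scale)

    session2 = []
    for m, mag, sc in zip(session1, mags, scales):
        c2 = np.asarray(m.center)
        if mag > 0:
            for _ in range(200):  # keep the displaced centre inside the arena
                theta = rng.uniform(0, 2 * np.pi)
                cand = np.asarray(m.center) + mag * np.array([np.cos(theta), np.sin(theta)])
                if arena.contains(cand[None, :])[0]:
                    c2 = cand
                    break
            else:
                c2 = np.clip(np.asarray(m.center) + mag * np.array([1.0, 0.0]),
                             [-w / 2, -h / 2], [w / 2, h / 2])
        session2.append(PlaceFieldModel(tuple(c2), m.width, m.peak_rate * sc,
                                        m.baseline_rate))
    return PlaceFieldEnsemble(arena, session1, session2)


def generate_spikes(
    model: PlaceFieldModel | Sequence[PlaceFieldModel],
    trajectory: Trajectory,
    seed: int | np.random.Generator = 0,
    session: str = "",
) -> SpikeTrainSet:
    """Inhomogeneous-Poisson spike trains driven by place-field rate maps.

    The rate at each tracker sample is lambda(x(t)); spike counts per step
    are Poisson(lambda * dt) with spikes placed uniformly within the step.
    """
    models = [model] if isinstance(model, PlaceFieldModel) else list(model)
    for m in models:
        if not trajectory.arena.contains(np.asarray(m.center)[None, :])[0]:
            raise ValueError("place-field centre lies outside the trajectory's arena")
    rng = np.random.default_rng(seed)
    trains: dict[int, np.ndarray] = {}
    n = len(trajectory)
    dt = trajectory.step
    for uid, m in enumerate(models):
        if n < 2:
            trains[uid] = np.empty(0)
            continue
        lam = m.rate(trajectory.positions)
        counts = rng.poisson(lam * dt)
        total = int(counts.sum())
        reps = np.repeat(trajectory.times, counts)
        times = np.sort(reps + rng.uniform(0, dt, total))
        trains[uid] = times
    classes = {uid: UnitClass.PYRAMIDAL for uid in trains}
    return SpikeTrainSet(trains, classes, session)


def _pink_noise(n: int, exponent: float, rng: np.random.Generator) -> np.ndarray:
    """1/f^(exponent/2) amplitude-shaped Gaussian noise, unit variance."""
    white = rng.normal(0, 1, n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0)
    shaping = np.ones_like(f)
    nz = f > 0
    shaping[nz] = 1.0 / np.maximum(f[nz], f[nz].min()) ** (exponent / 2)
    shaping[0] = 0.0
    out = np.fft.irfft(spec * shaping, n)
    sd = out.std()
    return out / sd if sd > 0 else out


def simulate_sleep_lfp(
    duration: float,
    ripple_rate: float = 0.3,
    ripple_freq: float = 160.0,
    ripple_cycles: float = 7.0,
    ripple_amp_sd: float = 5.0,
    sharp_wave_amp: float = 4.0,
    noise_params: NoiseParams = NoiseParams(),
    sampling_rate: float = 2000.0,
    seed: int | np.random.Generator = 0,
    min_separation: float = 0.3,
) -> tuple[LfpRecording, RippleEventTable]:
    """Two-channel sleep LFP with injected SWR events and their ground truth.

    The pyramidal-layer channel carries Gaussian-enveloped ripple bursts at
    ``ripple_freq`` on top of 1/f background; the radiatum channel carries a
    concurrent negative sharp wave. Ripple amplitude is ``ripple_amp_sd``
    times the SD of the band-passed (100-250 Hz) background.
    """
    if ripple_freq >= sampling_rate / 2:
        raise ValueError("ripple frequency must be below the Nyquist frequency")
    if duration <= 0:
        raise ValueError("duration must be positive")
    rng = np.random.default_rng(seed)
    fs = sampling_rate
    n = int(round(duration * fs))
    t = np.arange(n) / fs

    pyr = _pink_noise(n, noise_params.exponent, rng) * noise_params.sd
    rad = _pink_noise(n, noise_params.exponent, rng) * noise_params.sd

    # in-band background SD sets the injected amplitude scale
    sos = signal.butter(2, [100, 250], btype="bandpass", fs=fs, output="sos")
    band_sd = float(np.std(signal.sosfiltfilt(sos, pyr))) if noise_params.sd > 0 else 0.0
    # with no background the amplitude reference defaults to 200 int16 units
    amp = ripple_amp_sd * band_sd if band_sd > 0 else ripple_amp_sd * 200.0
    sw_amp = sharp_wave_amp * noise_params.sd

    event_dur = ripple_cycles / ripple_freq
    sigma_env = event_dur / 4.0        # +/-2 sigma spans the burst
    sigma_sw = 0.012
    margin = 2 * sigma_env + 0.1

    centers: list[float] = []
    if ripple_rate > 0:
        tc = margin
        while True:
            tc += rng.exponential(1.0 / ripple_rate)
            if tc >= duration - margin:
                break
            if centers and tc - centers[-1] < min_separation:
                continue
            centers.append(tc)

    for tc in centers:
        i0 = max(0, int((tc - 4 * sigma_env) * fs))
        i1 = min(n, int((tc + 4 * sigma_env) * fs) + 1)
        tt = t[i0:i1] - tc
        phase = rng.uniform(0, 2 * np.pi)
        pyr[i0:i1] += amp * np.exp(-tt**2 / (2 * sigma_env**2)) * np.sin(
            2 * np.pi * ripple_freq * tt + phase)
        j0 = max(0, int((tc - 4 * sigma_sw) * fs))
        j1 = min(n, int((tc + 4 * sigma_sw) * fs) + 1)
        ts = t[j0:j1] - tc
        rad[j0:j1] -= sw_amp * np.exp(-ts**2 / (2 * sigma_sw**2))

    centers_arr = np.asarray(centers)
    truth = RippleEventTable.from_arrays(
        onset=centers_arr - 2 * sigma_env,
        offset=centers_arr + 2 * sigma_env,
        peak_time=centers_arr,
        peak_frequency=np.full(len(centers), ripple_freq),
        amplitude=np.full(len(centers), amp),
        provenance=EventProvenance.GROUND_TRUTH,
    )
    lfp = LfpRecording(
        np.vstack([pyr, rad]),
        sampling_rate=fs,
        channel_roles=[ChannelRole.PYRAMIDALE, ChannelRole.RADIATUM],
    )
    return lfp, truth


def apply_light_suppression(
    spikes: SpikeTrainSet,
    pulses: PulseTrain,
    suppression: float,
    rebound_params: ReboundParams | None = None,
    seed: int | np.random.Generator = 0,
) -> SpikeTrainSet:
    """Delete each in-pulse spike independently with probability
    ``suppression``; optionally add post-pulse rebound spikes."""
    if not 0.0 <= suppression <= 1.0:
        raise ValueError("suppression must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    out: dict[int, np.ndarray] = {}
    for uid, train in spikes.trains.items():
        inside = pulses.contains(train)
        if suppression > 0 and inside.any():
            kill = inside & (rng.random(len(train)) < suppression)
            kept = train[~kill]
        else:
            kept = train.copy()
        if rebound_params is not None and len(pulses):
            rp = rebound_params
            span = len(train) and (train[-1] - train[0])
            base_rate = len(train) / span if span else 0.0
            lam = rp.rate_factor * base_rate * rp.window
            extra_counts = rng.poisson(lam, len(pulses))
            extras = []
            for onset_off, k in zip(pulses.offsets, extra_counts):
                if k:
                    extras.append(onset_off + rng.uniform(0, rp.window, k))
            if extras:
                kept = np.sort(np.concatenate([kept, *extras]))
        out[uid] = kept
    return SpikeTrainSet(out, dict(spikes.unit_classes), spikes.session)


def regular_pulse_train(
    start: float,
    end: float,
    period: float = 3.0,
    duration: float = 0.5,
    intensity: str = "half",
) -> PulseTrain:
    """Regularly timed laser pulses, as used in the half-intensity control
    sleep that quantifies per-cell inhibition."""
    if period <= duration:
        raise ValueError("pulse period must exceed pulse duration")
    onsets = np.arange(start, end - duration, period)
    return PulseTrain(onsets, duration, mode="direct", intensity=intensity)


def day_schedule(
    presleep: float = 1200.0,
    exploration: float = 1440.0,
    sleep_block: float = 1200.0,
    n_sleep_blocks: int = 3,
    postsleep: float = 1200.0,
    laser_control: float = 1800.0,
) -> list[dict]:
    """The recording-day timeline: pre-sleep, exploration 1, sleep blocks
    with stimulation, exploration 2, post-sleep, half-intensity control
    sleep. Times are seconds of recorded data from day start."""
    rows = []
    t = 0.0

    def add(name: str, kind: str, dur: float) -> None:
        nonlocal t
        rows.append({"name": name, "kind": kind, "start": t, "end": t + dur})
        t += dur

    add("presleep", "presleep", presleep)
    add("exploration1", "exploration1", exploration)
    for i in range(n_sleep_blocks):
        add(f"sleep{i + 1}", "sleep_block", sleep_block)
    add("exploration2", "exploration2", exploration)
    add("postsleep", "postsleep", postsleep)
    add("laser_control", "laser_control_sleep", laser_control)
    return rows
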