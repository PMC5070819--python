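"""Occupancy-normalised firing-rate maps and per-cell map quality metrics.

Sparsity (Skaggs) measures how restrictedly in space a cell fires; spatial
coherence (Muller-Kubie style first-order autocorrelation) measures how
smooth and contiguous the place field is. Both are the standard CA1
place-cell quality metrics.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage, stats

from .core import Arena, OccupancyMap, RateMap, SpikeTrainSet, Trajectory


def _grid_edges(arena: Arena, bin_size: float) -> tuple[np.ndarray, np.ndarray]:
    w, h = arena.extent
    nx = max(1, int(np.ceil(w / bin_size)))
    ny = max(1, int(np.ceil(h / bin_size)))
    x_edges = -w / 2 + bin_size * np.arange(nx + 1)
    y_edges = -h / 2 + bin_size * np.arange(ny + 1)
    # make sure the last edge covers the wall despite rounding
    x_edges[-1] = max(x_edges[-1], w / 2)
    y_edges[-1] = max(y_edges[-1], h / 2)
    return x_edges, y_edges


def occupancy_map(
    trajectory: Trajectory,
    bin_size: float = 2.0,
    min_occupancy: float = 0.1,
    speed_threshold: float | None = 2.5,
) -> OccupancyMap:
    """Dwell time per square bin, optionally restricted to running samples
    (speed >= ``speed_threshold`` cm/s)."""
    if bin_size <= 0:
        raise ValueError("bin size must be positive")
    x_edges, y_edges = _grid_edges(trajectory.arena, bin_size)
    if len(trajectory) < 2:
        dwell = np.zeros((len(x_edges) - 1, len(y_edges) - 1))
        return OccupancyMap(x_edges, y_edges, dwell, dwell > np.inf, bin_size,
                            speed_threshold)
    pos = trajectory.positions
    step = trajectory.step
    if speed_threshold is not None:
        keep = trajectory.speeds >= speed_threshold
        pos = pos[keep]
    dwell, _, _ = np.histogram2d(pos[:, 0], pos[:, 1], bins=[x_edges, y_edges])
    dwell *= step
    valid = dwell >= min_occupancy
    return OccupancyMap(x_edges, y_edges, dwell, valid, bin_size, speed_threshold)


def rate_map(
    spike_times: np.ndarray,
    trajectory: Trajectory,
    occupancy: OccupancyMap,
    smoothing_sigma: float = 1.0,
) -> RateMap:
    """Spike count per bin divided by dwell time.

    Spikes are positioned by linear interpolation of the tracker at spike
    time, and pass the same speed filter as the occupancy. Smoothing applies
    a Gaussian kernel (sigma in bins) to counts and dwell separately before
    the division; ``rate_unsmoothed`` keeps the raw ratio.
    """
    t = np.asarray(spike_times, dtype=float)
    if len(trajectory) >= 2:
        t0, t1 = trajectory.times[0], trajectory.times[-1]
        t = t[(t >= t0) & (t <= t1)]
        if occupancy.speed_threshold is not None:
            t = t[trajectory.speed_at(t) >= occupancy.speed_threshold]
        pos = trajectory.position_at(t)
    else:
        pos = np.zeros((0, 2))
    counts, _, _ = np.histogram2d(pos[:, 0], pos[:, 1],
                                  bins=[occupancy.x_edges, occupancy.y_edges])
    dwell = occupancy.dwell
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = np.where(dwell > 0, counts / np.where(dwell > 0, dwell, 1), np.nan)
    raw = np.where(occupancy.valid, raw, np.nan)
    if smoothing_sigma > 0:
        sm_counts = ndimage.gaussian_filter(counts, smoothing_sigma)
        sm_dwell = ndimage.gaussian_filter(dwell, smoothing_sigma)
        with np.errstate(divide="ignore", invalid="ignore"):
            rate = np.where(sm_dwell > 0, sm_counts / np.where(sm_dwell > 0, sm_dwell, 1),
                            np.nan)
        rate = np.where(occupancy.valid, rate, np.nan)
    else:
        rate = raw.copy()
    return RateMap(rate, raw, occupancy.valid.copy(), smoothing_sigma,
                   occupancy.bin_size)


def sparsity(rmap: RateMap, occupancy: OccupancyMap) -> float:
    """Skaggs sparsity (sum p*r)^2 / sum p*r^2 over valid bins.

    p is the dwell fraction, r the bin firing rate. 1 for spatially uniform
    firing, 1/N when all firing is confined to one of N equally occupied
    bins; NaN when the cell never fires on the valid bins.
    """
    valid = rmap.valid & occupancy.valid & np.isfinite(rmap.rate)
    p = occupancy.dwell[valid]
    tot = p.sum()
    if tot == 0:
        return float("nan")
    p = p / tot
    r = rmap.rate[valid]
    denom = np.sum(p * r**2)
    if denom == 0:
        return float("nan")
    return float(np.sum(p * r) ** 2 / denom)


def coherence(rmap: RateMap, fisher_z: bool = False) -> float:
    """First-order spatial autocorrelation of the unsmoothed rate map.

    Pearson correlation, across valid bins, between each bin's rate and the
    mean rate of its available 8-neighbourhood. Positive for smooth,
    contiguous fields; NaN for maps with no rate variance.
    """
    r = rmap.rate_unsmoothed
    valid = rmap.valid & np.isfinite(r)
    filled = np.where(valid, r, 0.0)
    kernel = np.ones((3, 3))
    kernel[1, 1] = 0.0
    nb_sum = ndimage.convolve(filled, kernel, mode="constant", cval=0.0)
    nb_cnt = ndimage.convolve(valid.astype(float), kernel, mode="constant", cval=0.0)
    use = valid & (nb_cnt > 0)
    if use.sum() < 8:
        raise ValueError("need at least 8 valid bins with valid neighbours")
    center = r[use]
    nbr = nb_sum[use] / nb_cnt[use]
    if np.std(center) == 0 or np.std(nbr) == 0:
        return float("nan")
    rho = float(stats.pearsonr(center, nbr).statistic)
    return float(np.arctanh(np.clip(rho, -1 + 1e-12, 1 - 1e-12))) if fisher_z else rho


def session_rate_maps(
    spikes: SpikeTrainSet,
    trajectory: Trajectory,
    bin_size: float = 2.0,
    min_occupancy: float = 0.1,
    speed_threshold: float | None = 2.5,
    smoothing_sigma: float = 1.0,
) -> tuple[OccupancyMap, dict[int, RateMap]]:
    """Occupancy plus one rate map per unit for a single exploration."""
    occ = occupancy_map(trajectory, bin_size, min_occupancy, speed_threshold)
    maps = {
        uid: rate_map(train, trajectory, occ, smoothing_sigma)
        for uid, train in spikes.trains.items()
    }
    return occ, maps
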