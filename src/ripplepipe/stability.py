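"""Single-cell and ensemble stability between the two explorations.

Rate change RC = |f1 - f2| / (f1 + f2) covers both rate and global
remapping; the rate-map Pearson correlation quantifies spatial stability
(identical maps -> 1, unrelated maps -> ~0); pairwise cofiring
coefficients and their cross-session correlation quantify stability of the
population co-activation structure, compared across conditions with
Fisher's Z-test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .core import RateMap, SpikeTrainSet

logger = logging.getLogger(__name__)


@dataclass
class CofiringSet:
    """Per-pair cofiring coefficients for one session.

    The coefficient of an unordered cell pair is the Pearson correlation of
    the two units' spike-count vectors over temporal bins of ``bin_size``.
    """

    pairs: list[tuple[int, int]]
    coefficients: np.ndarray
    bin_size: float
    session: str = ""
    excluded: dict[tuple[int, int], str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if len(self.pairs) != len(self.coefficients):
            raise ValueError("one coefficient per pair required")
        if len(set(self.pairs)) != len(self.pairs):
            raise ValueError("pairs must be unique")
        finite = self.coefficients[np.isfinite(self.coefficients)]
        if len(finite) and (np.abs(finite) > 1 + 1e-9).any():
            raise ValueError("cofiring coefficients must lie in [-1, 1]")

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    def as_dict(self) -> dict[tuple[int, int], float]:
        return dict(zip(self.pairs, self.coefficients))


def rate_change(f1: float, f2: float) -> float:
    """RC = |f1 - f2| / (f1 + f2), in [0, 1]; NaN for a silent cell."""
    if f1 < 0 or f2 < 0:
        raise ValueError("firing rates must be non-negative")
    if f1 + f2 == 0:
        return float("nan")
    return abs(f1 - f2) / (f1 + f2)


def map_correlation(map1: RateMap, map2: RateMap, min_bins: int = 10) -> float:
    """Pearson correlation between congruent bins of two rate maps.

    Only bins valid in both maps enter; NaN when either map has zero
    variance over the joint bins or too few joint bins exist.
    """
    if map1.rate.shape != map2.rate.shape:
        raise ValueError("rate maps must share the same grid")
    joint = (map1.valid & map2.valid
             & np.isfinite(map1.rate) & np.isfinite(map2.rate))
    if joint.sum() < min_bins:
        return float("nan")
    a, b = map1.rate[joint], map2.rate[joint]
    if np.std(a) == 0 or np.std(b) == 0:
        return float("nan")
    return float(stats.pearsonr(a, b).statistic)


def binned_counts(
    spikes: SpikeTrainSet,
    start: float,
    end: float,
    bin_size: float,
) -> tuple[np.ndarray, list[int]]:
    """Spike counts per unit per temporal bin; shape (n_units, n_bins)."""
    if bin_size <= 0 or end <= start:
        raise ValueError("need positive bin size and end > start")
    edges = np.arange(start, end + bin_size / 2, bin_size)
    uids = spikes.unit_ids
    counts = np.vstack([
        np.histogram(spikes.trains[u], bins=edges)[0] for u in uids
    ]) if uids else np.zeros((0, len(edges) - 1))
    return counts, uids


def pairwise_cofiring(
    spikes: SpikeTrainSet,
    start: float,
    end: float,
    bin_size: float = 0.250,
    min_spikes: int = 10,
) -> CofiringSet:
    """Cofiring coefficient for every retained unordered cell pair.

    Units with fewer than ``min_spikes`` spikes in the session or with zero
    count variance are dropped (with the reason recorded in ``excluded``).
    """
    counts, uids = binned_counts(spikes, start, end, bin_size)
    if len(uids) < 2:
        raise ValueError("need at least two units")
    excluded: dict[tuple[int, int], str] = {}
    keep = []
    for i, u in enumerate(uids):
        n = counts[i].sum()
        if n < min_spikes:
            logger.info("unit %d dropped from cofiring: %d spikes < %d",
                        u, n, min_spikes)
        elif counts[i].std() == 0:
            logger.info("unit %d dropped from cofiring: zero count variance", u)
        else:
            keep.append(i)
    pairs: list[tuple[int, int]] = []
    coefs: list[float] = []
    for a_pos, i in enumerate(keep):
        for j in keep[a_pos + 1:]:
            r = float(stats.pearsonr(counts[i], counts[j]).statistic)
            pairs.append((uids[i], uids[j]))
            coefs.append(r)
    dropped = set(uids) - {uids[i] for i in keep}
    for u in dropped:
        for v in uids:
            if v != u:
                excluded[tuple(sorted((u, v)))] = f"unit {u} excluded"
    return CofiringSet(pairs, np.asarray(coefs), bin_size, spikes.session, excluded)


def cofiring_similarity(set1: CofiringSet, set2: CofiringSet) -> tuple[float, int]:
    """Correlation, across cell pairs, of the two sessions' cofiring
    coefficients; returns (r, n_pairs entering the correlation)."""
    d1, d2 = set1.as_dict(), set2.as_dict()
    common = [p for p in d1 if p in d2
              and np.isfinite(d1[p]) and np.isfinite(d2[p])]
    if len(common) < 3:
        raise ValueError("need at least 3 pairs valid in both sessions")
    a = np.array([d1[p] for p in common])
    b = np.array([d2[p] for p in common])
    return float(stats.pearsonr(a, b).statistic), len(common)


def fisher_z_compare(r1: float, n1: int, r2: float, n2: int) -> tuple[float, float]:
    """Fisher's Z-test for the difference of two independent Pearson
    correlations: Z = (atanh r1 - atanh r2) / sqrt(1/(n1-3) + 1/(n2-3)),
    with a two-sided normal p-value."""
    for r in (r1, r2):
        if abs(r) >= 1:
            raise ValueError("correlations must lie strictly inside (-1, 1)")
    for n in (n1, n2):
        if n <= 3:
            raise ValueError("need more than 3 observations per correlation")
    z = (np.arctanh(r1) - np.arctanh(r2)) / np.sqrt(1 / (n1 - 3) + 1 / (n2 - 3))
    p = 2 * stats.norm.sf(abs(z))
    return float(z), float(p)


def mean_rate(spike_times: np.ndarray, start: float, end: float) -> float:
    """Whole-session mean firing rate (Hz), speed filter off."""
    if end <= start:
        raise ValueError("end must exceed start")
    t = np.asarray(spike_times)
    return float(((t >= start) & (t < end)).sum() / (end - start))
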