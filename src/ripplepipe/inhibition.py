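"""Per-cell optogenetic inhibition testing and shared group statistics.

The inhibition of each unit is quantified from the half-intensity control
sleep: per light pulse, the spike count inside the pulse is paired with the
count in an equal-length window immediately before it, and the pairs are
tested with a two-sided Wilcoxon signed-rank test. Direction (inhibited /
disinhibited / unchanged) follows the sign of the median count difference.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core import PulseTrain

logger = logging.getLogger(__name__)


class Direction(str, enum.Enum):
    INHIBITED = "inhibited"
    DISINHIBITED = "disinhibited"
    UNCHANGED = "unchanged"


@dataclass
class PSTH:
    """Peri-pulse spike-time histogram, counts summed over pulses."""

    bin_edges: np.ndarray    # seconds relative to pulse onset
    counts: np.ndarray
    n_pulses: int
    bin_size: float

    @property
    def rate(self) -> np.ndarray:
        """Counts converted to firing rate (Hz) per bin."""
        return self.counts / (self.n_pulses * self.bin_size)


@dataclass
class PulseResponse:
    """One unit's response to the regular light pulses."""

    unit_id: int
    baseline_counts: np.ndarray
    pulse_counts: np.ndarray
    psth: PSTH
    p_value: float
    direction: Direction
    baseline_rate: float
    pulse_rate: float


@dataclass
class PopulationInhibitionSummary:
    n_cells: int
    fraction_inhibited: float
    fraction_disinhibited: float
    fraction_unchanged: float
    alpha: float

    def __post_init__(self) -> None:
        total = (self.fraction_inhibited + self.fraction_disinhibited
                 + self.fraction_unchanged)
        if self.n_cells and abs(total - 1) > 1e-9:
            raise ValueError("direction fractions must sum to 1")


def pulse_psth(
    spike_times: np.ndarray,
    pulses: PulseTrain,
    bin_size: float = 0.010,
    window: tuple[float, float] = (-0.5, 1.0),
) -> PSTH:
    """Spike counts in ``bin_size`` bins around every pulse onset.

    The window may be truncated (with a logged warning) if it spans
    neighbouring pulses.
    """
    if len(pulses) == 0:
        raise ValueError("need at least one pulse")
    lo, hi = window
    if len(pulses) > 1:
        min_gap = float(np.min(np.diff(pulses.onsets)))
        if hi - lo > min_gap:
            logger.warning("PSTH window %.3f s exceeds the %.3f s pulse period; "
                           "bins overlap neighbouring pulses", hi - lo, min_gap)
    # integer-multiple edges keep offset 0 an exact bin boundary
    edges = bin_size * np.arange(round(lo / bin_size),
                                 round(hi / bin_size) + 1)
    t = np.asarray(spike_times, dtype=float)
    counts = np.zeros(len(edges) - 1)
    for onset in pulses.onsets:
        rel = t[(t >= onset + lo) & (t < onset + hi)] - onset
        counts += np.histogram(rel, bins=edges)[0]
    return PSTH(edges, counts, len(pulses), bin_size)


def inhibition_test(
    spike_times: np.ndarray,
    pulses: PulseTrain,
    alpha: float = 0.05,
    unit_id: int = 0,
    psth_window: tuple[float, float] = (-0.5, 1.0),
) -> PulseResponse:
    """Paired Wilcoxon signed-rank test of in-pulse versus pre-pulse counts.

    The baseline window of each pulse is the pulse-length interval that
    immediately precedes the pulse onset. Zero-difference pairs are dropped
    (standard signed-rank convention); if every pair ties, the unit is
    reported unchanged with p = NaN.
    """
    if len(pulses) < 10:
        raise ValueError("need at least 10 pulses")
    t = np.sort(np.asarray(spike_times, dtype=float))
    dur = pulses.duration
    base = np.array([
        np.searchsorted(t, on) - np.searchsorted(t, on - dur)
        for on in pulses.onsets
    ])
    inside = np.array([
        np.searchsorted(t, on + dur) - np.searchsorted(t, on)
        for on in pulses.onsets
    ])
    psth = pulse_psth(t, pulses, window=psth_window)
    diffs = inside - base
    if np.all(diffs == 0):
        # every pair tied: no evidence of any effect. p is undefined when the
        # unit never fired at all; identical nonzero counts give p = 1.
        logger.info("unit %d: all pulse/baseline pairs tied; reported unchanged",
                    unit_id)
        p = float("nan") if np.all(inside == 0) and np.all(base == 0) else 1.0
        direction = Direction.UNCHANGED
    else:
        res = stats.wilcoxon(inside, base, zero_method="wilcox",
                             alternative="two-sided",
                             method="exact" if len(diffs) <= 25 else "approx")
        p = float(res.pvalue)
        med = float(np.median(diffs[diffs != 0]))
        if p >= alpha or med == 0:
            direction = Direction.UNCHANGED
        elif med < 0:
            direction = Direction.INHIBITED
        else:
            direction = Direction.DISINHIBITED
    n = len(pulses)
    return PulseResponse(
        unit_id=unit_id,
        baseline_counts=base,
        pulse_counts=inside,
        psth=psth,
        p_value=p,
        direction=direction,
        baseline_rate=float(base.sum() / (n * dur)),
        pulse_rate=float(inside.sum() / (n * dur)),
    )


def population_summary(
    responses: list[PulseResponse],
    alpha: float = 0.05,
) -> PopulationInhibitionSummary:
    """Fractions of units inhibited / disinhibited / unchanged."""
    if not responses:
        raise ValueError("need at least one response")
    n = len(responses)
    n_inh = sum(r.direction is Direction.INHIBITED for r in responses)
    n_dis = sum(r.direction is Direction.DISINHIBITED for r in responses)
    return PopulationInhibitionSummary(
        n_cells=n,
        fraction_inhibited=n_inh / n,
        fraction_disinhibited=n_dis / n,
        fraction_unchanged=(n - n_inh - n_dis) / n,
        alpha=alpha,
    )


def oneway_anova(*groups: np.ndarray) -> tuple[float, float]:
    """Classical one-way ANOVA across two or more groups -> (F, p)."""
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    for g in arrays:
        if len(g) < 2:
            raise ValueError("each group needs at least two values")
        if not np.isfinite(g).all():
            raise ValueError("groups must contain finite values")
    res = stats.f_oneway(*arrays)
    return float(res.statistic), float(res.pvalue)


def ks_test(sample1: np.ndarray, sample2: np.ndarray) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov test -> (D, p), asymptotic p-value."""
    a = np.asarray(sample1, dtype=float)
    b = np.asarray(sample2, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be non-empty")
    res = stats.ks_2samp(a, b, method="asymp")
    return float(res.statistic), float(res.pvalue)
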