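"""Shared fixtures: generated once per session, reused across test modules."""

import numpy as np
import pytest

from ripplepipe import detection, maps, synthetic


@pytest.fixture(scope="session")
def arena():
    return synthetic.DEFAULT_ARENA


@pytest.fixture(scope="session")
def exploration_trajectory(arena):
    """A full 24-min exploration at the default tracker rate."""
    return synthetic.simulate_trajectory(arena, 1440.0, 0.025, seed=1)


@pytest.fixture(scope="session")
def second_trajectory(arena):
    return synthetic.simulate_trajectory(arena, 1440.0, 0.025, seed=2)


@pytest.fixture(scope="session")
def sleep_recording():
    """Two minutes of default sleep LFP with ground-truth SWR events."""
    return synthetic.simulate_sleep_lfp(120.0, ripple_rate=0.5, seed=3)


@pytest.fixture(scope="session")
def detected_sleep(sleep_recording):
    """Filtered differential signal and the online detection products."""
    lfp, truth = sleep_recording
    filt = detection.ripple_bandpass(detection.differential_signal(lfp),
                                     lfp.sampling_rate)
    ttl, laser = detection.online_closed_loop(filt, lfp.sampling_rate)
    return {"lfp": lfp, "truth": truth, "filtered": filt, "ttl": ttl,
            "laser": laser}


@pytest.fixture(scope="session")
def zero_drift_sessions(arena, exploration_trajectory, second_trajectory):
    """30 perfectly stable cells observed in two independent explorations."""
    ens = synthetic.make_ensemble(
        30, arena, synthetic.StabilityParams(drift=0.0, rate_scale=1.0), seed=7)
    s1 = synthetic.generate_spikes(ens.session1, exploration_trajectory, seed=13,
                                   session="exploration1")
    s2 = synthetic.generate_spikes(ens.session2, second_trajectory, seed=14,
                                   session="exploration2")
    occ1, maps1 = maps.session_rate_maps(s1, exploration_trajectory)
    occ2, maps2 = maps.session_rate_maps(s2, second_trajectory)
    return {"ensemble": ens, "spikes": (s1, s2), "occupancy": (occ1, occ2),
            "maps": (maps1, maps2)}
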