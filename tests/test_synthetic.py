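"""The generators honour their stated laws: seed determinism, Poisson
statistics, geometric containment, and exact ground truth."""

import numpy as np
import pytest
from scipy import signal

from ripplepipe.core import Arena, ArenaShape, PulseTrain, SpikeTrainSet
from ripplepipe import synthetic
from ripplepipe.synthetic import (
    NoiseParams,
    SpeedParams,
    StabilityParams,
    apply_light_suppression,
    day_schedule,
    generate_spikes,
    make_ensemble,
    simulate_sleep_lfp,
    simulate_trajectory,
)


class TestTrajectory:
    def test_zero_duration_gives_empty_trajectory(self, arena):
        traj = simulate_trajectory(arena, 0.0, 0.025, seed=0)
        assert len(traj) == 0

    def test_zero_max_speed_freezes_the_walk(self, arena):
        traj = simulate_trajectory(arena, 10.0, 0.025,
                                   SpeedParams(max_speed=0.0), seed=0)
        assert np.all(traj.positions == traj.positions[0])

    def test_invalid_arguments_rejected(self, arena):
        with pytest.raises(ValueError):
            simulate_trajectory(arena, 10.0, -0.01)
        with pytest.raises(ValueError):
            simulate_trajectory(arena, -1.0, 0.025)

    def test_positions_stay_inside_rectangle_and_circle(self):
        rect = Arena(ArenaShape.RECTANGLE, (40.0, 60.0))
        circ = Arena(ArenaShape.CIRCLE, (50.0,))
        for arena in (rect, circ):
            traj = simulate_trajectory(arena, 120.0, 0.025, seed=5)
            assert arena.contains(traj.positions).all()

    def test_seed_determinism(self, arena):
        a = simulate_trajectory(arena, 30.0, 0.025, seed=9)
        b = simulate_trajectory(arena, 30.0, 0.025, seed=9)
        np.testing.assert_array_equal(a.positions, b.positions)

    def test_default_walk_covers_the_arena(self, exploration_trajectory):
        """24 min at default speeds visits >= 90% of 2-cm bins."""
        pos = exploration_trajectory.positions
        ix = np.clip(np.floor((pos[:, 0] + 30) / 2).astype(int), 0, 29)
        iy = np.clip(np.floor((pos[:, 1] + 30) / 2).astype(int), 0, 29)
        visited = len(set(zip(ix.tolist(), iy.tolist())))
        assert visited / 900 >= 0.90

    def test_mean_speed_near_requested(self, exploration_trajectory):
        assert np.mean(exploration_trajectory.speeds) == pytest.approx(8.0, rel=0.2)


class TestEnsemble:
    def test_zero_drift_unit_scale_is_identity(self, arena):
        ens = make_ensemble(10, arena, StabilityParams(0.0, 0.0, 1.0, 0.0), seed=0)
        for m1, m2 in zip(ens.session1, ens.session2):
            assert m1.center == m2.center
            assert m1.peak_rate == m2.peak_rate

    def test_single_cell_drift_magnitude_is_exact(self, arena):
        sigma = 5.0
        ens = make_ensemble(1, arena, StabilityParams(drift=5 * sigma), seed=1,
                            field_width=sigma)
        assert ens.drifts()[0] == pytest.approx(5 * sigma, abs=1e-9)

    def test_mixture_drift_histogram_is_bimodal(self, arena):
        """Half small-drift, half large-drift cells: recomputed distances
        cluster around the two requested magnitudes."""
        per_cell = np.array([2.0] * 50 + [20.0] * 50)
        ens = make_ensemble(100, arena, StabilityParams(drift=per_cell), seed=2)
        d = ens.drifts()
        assert np.all(np.abs(d[:50] - 2.0) < 1e-6)
        assert np.all(np.abs(d[50:] - 20.0) < 1e-6)

    def test_drift_beyond_arena_rejected(self, arena):
        with pytest.raises(ValueError):
            make_ensemble(5, arena, StabilityParams(drift=1000.0))

    def test_centers_inside_arena(self):
        circ = Arena(ArenaShape.CIRCLE, (40.0,))
        ens = make_ensemble(50, circ, StabilityParams(drift=10.0), seed=3)
        for m in ens.session1 + ens.session2:
            assert circ.contains(np.asarray(m.center)[None, :])[0]


class TestSpikes:
    def test_silent_model_gives_no_spikes(self, arena, exploration_trajectory):
        from ripplepipe.core import PlaceFieldModel
        m = PlaceFieldModel((0, 0), 5.0, peak_rate=0.0, baseline_rate=0.0)
        st = generate_spikes(m, exploration_trajectory, seed=0)
        assert st.n_spikes() == 0

    def test_homogeneous_rate_matches_poisson_count(self, arena):
        from ripplepipe.core import PlaceFieldModel
        traj = simulate_trajectory(arena, 600.0, 0.025, seed=4)
        m = PlaceFieldModel((0, 0), 5.0, peak_rate=0.0, baseline_rate=2.0)
        st = generate_spikes(m, traj, seed=5)
        # mean 1200, allow 4 sigma
        assert abs(st.n_spikes() - 1200) < 4 * np.sqrt(1200)

    def test_center_outside_arena_rejected(self, exploration_trajectory):
        from ripplepipe.core import PlaceFieldModel
        m = PlaceFieldModel((100.0, 0.0), 5.0, 10.0)
        with pytest.raises(ValueError):
            generate_spikes(m, exploration_trajectory)

    def test_rate_fidelity_in_field_center(self, arena):
        """Empirical rate in the field-centre bin converges to the model
        rate (10% tolerance over 30 min)."""
        from ripplepipe.core import PlaceFieldModel
        traj = simulate_trajectory(arena, 1800.0, 0.025, seed=6)
        m = PlaceFieldModel((0.0, 0.0), 5.0, peak_rate=10.0, baseline_rate=0.5)
        st = generate_spikes(m, traj, seed=7)
        t = st.trains[0]
        pos = traj.positions
        in_bin = (np.abs(pos[:, 0]) < 1.0) & (np.abs(pos[:, 1]) < 1.0)
        dwell = in_bin.sum() * traj.step
        spike_pos = traj.position_at(t)
        n_in = ((np.abs(spike_pos[:, 0]) < 1.0)
                & (np.abs(spike_pos[:, 1]) < 1.0)).sum()
        expected = np.mean(m.rate(pos[in_bin]))
        assert n_in / dwell == pytest.approx(expected, rel=0.10)

    def test_seed_determinism(self, arena, exploration_trajectory):
        from ripplepipe.core import PlaceFieldModel
        m = PlaceFieldModel((5.0, -5.0), 5.0, 8.0, 0.1)
        a = generate_spikes(m, exploration_trajectory, seed=11)
        b = generate_spikes(m, exploration_trajectory, seed=11)
        np.testing.assert_array_equal(a.trains[0], b.trains[0])


class TestSleepLfp:
    def test_zero_rate_gives_pure_background(self):
        lfp, truth = simulate_sleep_lfp(10.0, ripple_rate=0.0, seed=0)
        assert len(truth) == 0
        lfp2, _ = simulate_sleep_lfp(10.0, ripple_rate=0.0, seed=0)
        np.testing.assert_array_equal(lfp.samples, lfp2.samples)

    def test_event_count_follows_poisson_law(self, sleep_recording):
        _, truth = sleep_recording
        # 120 s at 0.5/s -> ~60 minus refractory losses; 4-sigma band
        assert abs(len(truth) - 60) < 4 * np.sqrt(60) + 10

    def test_single_event_power_concentrates_at_ripple_freq(self):
        lfp, truth = simulate_sleep_lfp(
            6.0, ripple_rate=0.4, ripple_freq=160.0, seed=12,
            noise_params=NoiseParams(sd=0.0))
        assert len(truth) >= 1
        pyr = lfp.channel("pyramidale").astype(float)
        f, p = signal.periodogram(pyr, lfp.sampling_rate)
        sel = f >= 50
        assert f[sel][np.argmax(p[sel])] == pytest.approx(160.0, abs=5.0)

    def test_nyquist_violation_rejected(self):
        with pytest.raises(ValueError):
            simulate_sleep_lfp(10.0, ripple_freq=1100.0, sampling_rate=2000.0)

    def test_ground_truth_envelope_exceeds_background(self, sleep_recording):
        """Every injected ripple's 100-250 Hz envelope peak beats the
        background envelope's 99th percentile."""
        lfp, truth = sleep_recording
        fs = lfp.sampling_rate
        sos = signal.butter(2, [100, 250], btype="bandpass", fs=fs, output="sos")
        env = np.abs(signal.sosfiltfilt(sos, lfp.channel("pyramidale")))
        in_event = np.zeros(len(env), dtype=bool)
        for on, off in zip(truth.onsets, truth.offsets):
            in_event[int(on * fs):int(off * fs) + 1] = True
        q99 = np.quantile(env[~in_event], 0.99)
        for on, off in zip(truth.onsets, truth.offsets):
            assert env[int(on * fs):int(off * fs) + 1].max() > q99


@pytest.fixture(scope="module")
def train_and_pulses():
    rng = np.random.default_rng(20)
    train = np.sort(rng.uniform(0, 600, 3000))
    pulses = synthetic.regular_pulse_train(0, 600, period=3.0, duration=0.5)
    return SpikeTrainSet({0: train}), pulses


class TestSuppression:
    def test_zero_suppression_is_identity(self, train_and_pulses):
        spikes, pulses = train_and_pulses
        out = apply_light_suppression(spikes, pulses, 0.0, seed=0)
        np.testing.assert_array_equal(out.trains[0], spikes.trains[0])

    def test_full_suppression_empties_pulse_windows(self, train_and_pulses):
        spikes, pulses = train_and_pulses
        out = apply_light_suppression(spikes, pulses, 1.0, seed=0)
        assert not pulses.contains(out.trains[0]).any()

    def test_partial_suppression_is_binomial(self, train_and_pulses):
        spikes, pulses = train_and_pulses
        n_in = int(pulses.contains(spikes.trains[0]).sum())
        out = apply_light_suppression(spikes, pulses, 0.8, seed=1)
        survived = int(pulses.contains(out.trains[0]).sum())
        expect = 0.2 * n_in
        sd = np.sqrt(n_in * 0.2 * 0.8)
        assert abs(survived - expect) < 4 * sd

    def test_out_of_range_suppression_rejected(self, train_and_pulses):
        spikes, pulses = train_and_pulses
        with pytest.raises(ValueError):
            apply_light_suppression(spikes, pulses, 1.5)

    def test_rebound_adds_post_pulse_spikes(self, train_and_pulses):
        spikes, pulses = train_and_pulses
        out = apply_light_suppression(
            spikes, pulses, 1.0,
            rebound_params=synthetic.ReboundParams(0.05, 10.0), seed=2)
        post = PulseTrain(pulses.offsets, 0.05)
        assert post.contains(out.trains[0]).sum() > post.contains(spikes.trains[0]).sum()


def test_day_schedule_order_matches_paradigm():
    rows = day_schedule()
    kinds = [r["kind"] for r in rows]
    assert kinds == ["presleep", "exploration1", "sleep_block", "sleep_block",
                     "sleep_block", "exploration2", "postsleep",
                     "laser_control_sleep"]
    starts = [r["start"] for r in rows]
    assert starts == sorted(starts)
    assert all(r["end"] > r["start"] for r in rows)
    # three recorded 20-min sleep blocks = 60 min of sleep data
    assert sum(r["end"] - r["start"] for r in rows if r["kind"] == "sleep_block") == 3600
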