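"""Emulated closed-loop detector: causality, refractoriness, the delayed
control mode, and the non-stringent offline detector."""

import numpy as np
import pytest
from scipy import signal

from ripplepipe.core import ChannelRole, LfpRecording, RippleEventTable
from ripplepipe.detection import (
    DetectorConfig,
    OfflineDetectorParams,
    differential_signal,
    evaluate_detection,
    offline_detect,
    online_closed_loop,
    ripple_bandpass,
)
from ripplepipe import synthetic

FS = 2000.0


def _lfp(pyr, rad, fs=FS):
    return LfpRecording(np.vstack([pyr, rad]), fs,
                        [ChannelRole.PYRAMIDALE, ChannelRole.RADIATUM])


class TestDifferential:
    def test_identical_channels_cancel(self):
        x = np.random.default_rng(0).normal(0, 100, 4000)
        assert np.all(differential_signal(_lfp(x, x)) == 0)

    def test_zero_radiatum_passes_pyramidale(self):
        x = np.random.default_rng(1).normal(0, 100, 4000)
        lfp = _lfp(x, np.zeros_like(x))
        np.testing.assert_allclose(differential_signal(lfp),
                                   lfp.channel("pyramidale"))

    def test_missing_role_rejected(self):
        rec = LfpRecording(np.zeros((2, 100)), FS,
                           [ChannelRole.OTHER, ChannelRole.RADIATUM])
        with pytest.raises(ValueError):
            differential_signal(rec)

    def test_differential_boosts_event_envelope(self):
        """Ripple on pyramidale plus sharp wave on radiatum: the differential
        band-passed envelope at the event is at least each channel's own."""
        lfp, truth = synthetic.simulate_sleep_lfp(30.0, ripple_rate=0.5, seed=5)
        fs = lfp.sampling_rate
        sos = signal.butter(2, [100, 250], btype="bandpass", fs=fs, output="sos")

        def peak_env(x, on, off):
            env = np.abs(signal.sosfiltfilt(sos, x))
            return env[int(on * fs):int(off * fs) + 1].max()

        diff = differential_signal(lfp)
        pyr = lfp.channel("pyramidale")
        rad = lfp.channel("radiatum")
        on, off = truth.onsets[0], truth.offsets[0]
        assert peak_env(diff, on, off) >= 0.8 * peak_env(pyr, on, off)
        assert peak_env(diff, on, off) >= peak_env(rad, on, off)


class TestBandpass:
    def test_center_frequency_passes_more_than_50hz(self):
        t = np.arange(0, 2, 1 / FS)
        out150 = ripple_bandpass(np.sin(2 * np.pi * 150 * t), FS)
        out50 = ripple_bandpass(np.sin(2 * np.pi * 50 * t), FS)
        assert np.abs(out150[2000:]).max() > np.abs(out50[2000:]).max()

    def test_dc_is_rejected(self):
        out = ripple_bandpass(np.ones(8000), FS)
        assert np.abs(out[-1000:]).max() < 1e-6

    def test_white_noise_power_lands_in_the_passband(self):
        """Parseval check: the in-band share of the output power matches
        the filter's analytic |H|^2 integral ratio."""
        x = np.random.default_rng(2).normal(0, 1, 2**16)
        y = ripple_bandpass(x, FS)
        f, p = signal.periodogram(y, FS)
        inband = (f >= 100) & (f <= 200)
        measured = p[inband].sum() / p.sum()
        sos = signal.butter(2, [100, 200], btype="bandpass", fs=FS, output="sos")
        w, h = signal.sosfreqz(sos, worN=8192, fs=FS)
        h2 = np.abs(h) ** 2
        analytic = h2[(w >= 100) & (w <= 200)].sum() / h2.sum()
        assert measured == pytest.approx(analytic, rel=0.05)
        assert measured > 0.5

    def test_band_above_nyquist_rejected(self):
        with pytest.raises(ValueError):
            ripple_bandpass(np.zeros(100), 300.0, DetectorConfig())

    def test_gain_applied(self):
        t = np.arange(0, 2, 1 / FS)
        x = np.sin(2 * np.pi * 150 * t)
        g1 = ripple_bandpass(x, FS, DetectorConfig(gain=1.0))
        g10 = ripple_bandpass(x, FS, DetectorConfig(gain=10.0))
        np.testing.assert_allclose(g10, 10 * g1)


class TestClosedLoop:
    def test_subthreshold_signal_triggers_nothing(self):
        x = 0.1 * np.ones(4000)
        ttl, laser = online_closed_loop(x, FS, threshold=1.0)
        assert len(ttl) == 0 and len(laser) == 0

    def test_delayed_laser_onsets_shifted_exactly_1320ms(self, detected_sleep):
        filt = detected_sleep["filtered"]
        cfg = DetectorConfig()
        ttl, laser = online_closed_loop(filt, FS, cfg, mode="delayed")
        np.testing.assert_allclose(laser.onsets, ttl.onsets + 1.32)

    def test_crossings_inside_active_pulse_do_not_retrigger(self):
        x = np.zeros(int(FS))
        i1, i2 = 1000, 1000 + int(0.050 * FS)  # 50 ms apart
        x[i1] = x[i2] = 10.0
        ttl, _ = online_closed_loop(x, FS, threshold=5.0)
        assert len(ttl) == 1
        assert ttl.onsets[0] == pytest.approx(i1 / FS)
        # a crossing after the pulse does retrigger
        x[i1 + int(0.250 * FS)] = 10.0
        ttl2, _ = online_closed_loop(x, FS, threshold=5.0)
        assert len(ttl2) == 2

    def test_causality_no_ttl_before_crossing(self, detected_sleep):
        filt = detected_sleep["filtered"]
        thr = DetectorConfig().threshold_sd * np.std(filt)
        first = np.flatnonzero(np.abs(filt) >= thr)[0] / FS
        assert detected_sleep["ttl"].onsets[0] >= first - 1e-9

    def test_energy_parity_of_direct_and_delayed_modes(self, detected_sleep):
        """Control mode delivers the same number and total duration of
        pulses, hence the same light energy."""
        filt = detected_sleep["filtered"]
        ttl_d, laser_d = online_closed_loop(filt, FS, mode="direct")
        ttl_c, laser_c = online_closed_loop(filt, FS, mode="delayed")
        assert len(laser_d) == len(laser_c)
        assert laser_d.total_duration == laser_c.total_duration

    def test_trigger_within_two_ripple_cycles(self, detected_sleep):
        """TTL onset falls within 2 ripple cycles of the first
        suprathreshold cycle of each detected event."""
        filt = detected_sleep["filtered"]
        truth = detected_sleep["truth"]
        ttl = detected_sleep["ttl"]
        thr = DetectorConfig().threshold_sd * np.std(filt)
        checked = 0
        for on, off in zip(truth.onsets, truth.offsets):
            seg = np.abs(filt[int(on * FS):int(off * FS)])
            idx = np.flatnonzero(seg >= thr)
            if not len(idx):
                continue
            first = on + idx[0] / FS
            cand = ttl.onsets[(ttl.onsets >= on - 0.05) & (ttl.onsets <= off + 0.05)]
            if not len(cand):
                continue
            checked += 1
            assert cand[0] - first <= 2 / 160.0 + 1e-9
        assert checked >= 10


class TestOfflineDetect:
    def test_noise_only_high_threshold_near_empty(self):
        lfp, _ = synthetic.simulate_sleep_lfp(60.0, ripple_rate=0.0, seed=8)
        table = offline_detect(lfp, OfflineDetectorParams(threshold_sd=6.0))
        assert len(table) <= 2  # empirical false-positive allowance

    def test_single_ripple_detected_once(self):
        lfp, truth = synthetic.simulate_sleep_lfp(
            20.0, ripple_rate=0.08, seed=30)
        assert len(truth) >= 1
        table = offline_detect(lfp)
        on, off = truth.onsets[0], truth.offsets[0]
        hits = [(o, f) for o, f in zip(table.onsets, table.offsets)
                if o < off + 0.02 and f > on - 0.02]
        assert len(hits) == 1

    def test_truncated_event_still_detected_at_low_threshold(self, detected_sleep):
        """Blockade destroys the oscillation ~2 cycles after the detector
        fires; the non-stringent offline detector still finds the
        low-amplitude remnant that precedes the cut."""
        lfp = detected_sleep["lfp"]
        truth = detected_sleep["truth"]
        ttl = detected_sleep["ttl"]
        fs = lfp.sampling_rate
        samples = lfp.samples.astype(float)
        for on in ttl.onsets:  # emulate the light pulse killing the ripple
            cut = int((on + 2 / 160.0) * fs)
            end = int((on + 0.1) * fs)
            samples[0, cut:end] = 0.0
        trunc = LfpRecording(samples, fs, lfp.channel_roles)
        table = offline_detect(trunc, OfflineDetectorParams(threshold_sd=2.0))
        # restrict scoring to the truth events the online detector truncated
        hit = [bool(np.any((ttl.onsets >= on) & (ttl.onsets <= off + 0.02)))
               for on, off in zip(truth.onsets, truth.offsets)]
        truncated = RippleEventTable(truth.events[np.array(hit)], truth.provenance)
        ev = evaluate_detection(table, truncated, tolerance=0.05)
        assert ev.n_truth >= 10
        assert ev.recall >= 0.7

    def test_empty_signal_gives_empty_table(self):
        rec = LfpRecording(np.zeros((2, 0)), FS,
                           [ChannelRole.PYRAMIDALE, ChannelRole.RADIATUM])
        assert len(offline_detect(rec)) == 0

    def test_offline_online_concordance(self, detected_sleep):
        """On untruncated data, offline events cover >= 95% of the events
        that triggered an online TTL."""
        table = offline_detect(detected_sleep["lfp"])
        ttl = detected_sleep["ttl"]
        truth = detected_sleep["truth"]
        triggering = [on for on, off in zip(truth.onsets, truth.offsets)
                      if np.any((ttl.onsets >= on) & (ttl.onsets <= off + 0.02))]
        assert len(triggering) >= 10
        covered = sum(
            bool(np.any((table.onsets <= on + 0.05) & (table.offsets >= on)))
            for on in triggering)
        assert covered / len(triggering) >= 0.95


class TestEvaluate:
    def test_perfect_detection(self):
        truth = RippleEventTable.from_arrays([1.0, 2.0], [1.05, 2.05])
        ev = evaluate_detection(truth, truth)
        assert ev.precision == 1 and ev.recall == 1
        assert np.all(ev.latencies == 0)

    def test_empty_detection_reports_nan_precision(self):
        truth = RippleEventTable.from_arrays([1.0], [1.05])
        det = RippleEventTable.from_arrays([], [])
        ev = evaluate_detection(det, truth)
        assert ev.recall == 0 and np.isnan(ev.precision) and ev.n_detected == 0

    def test_constant_shift_shows_up_as_latency(self):
        rng = np.random.default_rng(3)
        onsets = np.sort(rng.uniform(0, 500, 100))
        onsets = onsets[np.concatenate([[True], np.diff(onsets) > 0.2])]
        truth = RippleEventTable.from_arrays(onsets, onsets + 0.05)
        det = RippleEventTable.from_arrays(onsets + 0.005, onsets + 0.055)
        ev = evaluate_detection(det, truth, tolerance=0.05)
        assert ev.recall == 1.0
        assert ev.mean_latency == pytest.approx(0.005, abs=1e-9)
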