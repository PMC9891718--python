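import numpy as np
import pytest

from flagcal.core import Kymograph, SpikeEvent
from flagcal.synth import SynthConfig, make_dual_kymograph, make_ift_kymograph
from flagcal import dual_channel as dc, kymo_ca


def ev(onset, end, area=1000.0):
    return SpikeEvent(
        onset_s=onset,
        end_s=end,
        peak_time_s=(onset + end) / 2,
        peak_amplitude=area,
        area=area,
    )


class TestBleedthrough:
    def test_zero_fraction_identity(self, dual_dataset):
        _, g, m, _ = dual_dataset
        out = dc.bleedthrough_correct(g, m, 0.0)
        assert np.array_equal(out.intensity, g.intensity)

    def test_known_mixing_recovered_exactly(self):
        cfg = SynthConfig(noise_sd=0.0, bleedthrough_fraction=0.2)
        g, m, truth = make_dual_kymograph(cfg, 5)
        out = dc.bleedthrough_correct(g, m, 0.2)
        assert np.allclose(out.intensity, truth.clean_ca, atol=1e-10)

    def test_correction_is_invertible(self, dual_dataset):
        _, g, m, _ = dual_dataset
        out = dc.bleedthrough_correct(g, m, 0.2)
        back = out.intensity + 0.2 * m.intensity
        assert np.allclose(back, g.intensity, atol=1e-10)

    def test_shape_mismatch_rejected(self, dual_dataset):
        _, g, m, _ = dual_dataset
        small = Kymograph(m.intensity[:-1, :])
        with pytest.raises(ValueError, match="shape"):
            dc.bleedthrough_correct(g, small)

    def test_false_spikes_colocalize_with_ift(self):
        # without correction, a spike-free GCaMP channel inherits "events"
        # from the IFT channel wherever bright trains pass
        cfg = SynthConfig(spike_rate=0.0, bleedthrough_fraction=0.2, noise_sd=2.0,
                          train_intensity_mean=400.0)
        g, m, truth = make_dual_kymograph(cfg, 3)
        raw_events = kymo_ca.detect_spikes(kymo_ca.smooth(g))
        corrected = dc.bleedthrough_correct(g, m, 0.2)
        corr_events = kymo_ca.detect_spikes(kymo_ca.smooth(corrected))
        assert len(corr_events) < max(len(raw_events), 1)


class TestSelectBursts:
    def test_isolated_large_burst_selected(self):
        events = [ev(30.0, 31.0, area=5000.0)]
        assert dc.select_bursts(events, 60.0) == [30.0]

    def test_small_event_before_burst_disqualifies(self):
        events = [ev(26.0, 26.5, area=100.0), ev(30.0, 31.0, area=5000.0)]
        assert dc.select_bursts(events, 60.0) == []

    def test_small_area_burst_rejected(self):
        assert dc.select_bursts([ev(30.0, 31.0, area=1500.0)], 60.0) == []

    def test_merged_events_pool_their_area(self):
        events = [ev(30.0, 30.6, area=1200.0), ev(31.0, 31.5, area=1200.0)]
        assert dc.select_bursts(events, 60.0) == [30.0]

    def test_window_must_fit_in_movie(self):
        assert dc.select_bursts([ev(9.0, 10.0, area=5000.0)], 60.0) == []
        assert dc.select_bursts([ev(50.0, 51.0, area=5000.0)], 60.0) == []

    def test_constructed_mixture(self):
        events = [
            ev(15.0, 16.0, 5000.0),   # qualifies
            ev(20.0, 20.5, 90.0),     # spoils the next one
            ev(24.0, 25.0, 5000.0),   # rejected: quiet violated
            ev(40.0, 41.0, 5000.0),   # qualifies
            ev(60.0, 61.0, 1000.0),   # rejected: area
            ev(80.0, 81.0, 5000.0),   # qualifies
        ]
        assert dc.select_bursts(events, 120.0) == [15.0, 40.0, 80.0]


class TestWindowedMetrics:
    def test_out_of_range_onset_raises(self, dual_dataset):
        _, g, m, truth = dual_dataset
        with pytest.raises(ValueError, match="window out of range"):
            dc.windowed_metrics(g, m, truth.trajectories, 5.0, events=[])
        with pytest.raises(ValueError, match="window out of range"):
            dc.windowed_metrics(g, m, truth.trajectories, m.duration_s - 5.0, events=[])

    def test_time_shift_equivariance(self):
        cfg = SynthConfig(duration=90.0)
        kymo, truth = make_ift_kymograph(cfg, 5)
        m1 = dc.windowed_metrics(kymo, kymo, truth.trajectories, 30.0, events=[])
        # shift both channels and all trajectories by 10 s
        shift_s = 10.0
        shift_f = int(shift_s / cfg.frame_interval)
        pad = np.full((kymo.n_rows, shift_f), cfg.background)
        shifted = Kymograph(
            np.concatenate([pad, kymo.intensity], axis=1),
            pixel_size=kymo.pixel_size,
            frame_interval=kymo.frame_interval,
        )
        moved = []
        for t in truth.trajectories:
            import copy

            t2 = copy.deepcopy(t)
            t2.points[:, 0] += shift_f
            moved.append(t2)
        m2 = dc.windowed_metrics(shifted, shifted, moved, 30.0 + shift_s, events=[])
        assert np.allclose(m1.injection_intensity, m2.injection_intensity)
        assert np.allclose(m1.returning_intensity, m2.returning_intensity)
        assert np.allclose(m1.anterograde_frequency, m2.anterograde_frequency)

    def test_reactivation_signature(self, dual_dataset):
        # spike-released pauses: retrograde speed jumps at the burst window,
        # returning trains surge just after, and the untracked accumulated
        # material (the operational background) clears
        cfg, g, m, truth = dual_dataset
        corrected = dc.bleedthrough_correct(g, m, cfg.bleedthrough_fraction)
        events = kymo_ca.detect_spikes(kymo_ca.smooth(corrected))
        onsets = dc.select_bursts(events, corrected.duration_s)
        assert onsets, "the reactivation scenario must contain usable bursts"
        n_sig = 0
        for onset in onsets:
            wm = dc.windowed_metrics(corrected, m, truth.trajectories, onset, events=events)
            vr = wm.retrograde_speed
            rises = (
                np.isfinite(vr[1]) and np.isfinite(vr[2]) and vr[2] > vr[1]
                and max(wm.returning_intensity[2:4]) > max(wm.returning_intensity[:2])
                and np.mean(wm.background_intensity[2:]) < np.mean(wm.background_intensity[:2])
            )
            n_sig += rises
        assert n_sig == len(onsets)

    def test_ca_influx_sum_uses_onset_window(self, dual_dataset):
        cfg, g, m, truth = dual_dataset
        corrected = dc.bleedthrough_correct(g, m, cfg.bleedthrough_fraction)
        events = kymo_ca.detect_spikes(kymo_ca.smooth(corrected))
        onsets = dc.select_bursts(events, corrected.duration_s)
        wm = dc.windowed_metrics(corrected, m, truth.trajectories, onsets[0], events=events)
        # quiet period before the burst: windows a and b carry no influx
        assert wm.ca_influx_sum[0] == 0.0 and wm.ca_influx_sum[1] == 0.0
        assert wm.ca_influx_sum[2] > 0.0


class TestPairedWindowTest:
    def test_identical_columns_accept(self):
        m = np.tile(np.arange(8.0)[:, None], (1, 5))
        t, p, deg = dc.paired_window_test(m)
        assert np.all(p == 1.0) and not deg.any()

    def test_constant_shift_zero_variance_flagged(self):
        m = np.tile(np.arange(8.0)[:, None], (1, 5)) + np.arange(5.0)[None, :]
        t, p, deg = dc.paired_window_test(m)
        assert deg.all()

    def test_shifted_column_detected(self):
        rng = np.random.default_rng(0)
        m = rng.normal(0, 1, (25, 5))
        m[:, 2] += 3.0
        t, p, _ = dc.paired_window_test(m)
        assert p[1] < 0.001 and p[2] < 0.001  # (b,c) and (c,d) both jump

    def test_null_type_one_error_calibrated(self):
        # iid null matrices: each adjacent-pair test rejects at its level
        rng = np.random.default_rng(1)
        rej = np.zeros(4)
        n_rep = 1000
        for _ in range(n_rep):
            _, p, deg = dc.paired_window_test(rng.normal(0, 1, (29, 5)))
            rej += (p < 0.05) & ~deg
        assert np.all(np.abs(rej / n_rep - 0.05) < 0.02)

    def test_wrong_shape_rejected(self):
        with pytest.raises(ValueError):
            dc.paired_window_test(np.zeros((4, 3)))
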