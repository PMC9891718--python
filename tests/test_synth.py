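import numpy as np
import pytest

from flagcal.core import ANTEROGRADE, RETROGRADE
from flagcal.synth import (
    SynthConfig,
    make_ca_kymograph,
    make_dual_kymograph,
    make_ift_kymograph,
    make_length_series,
)
from flagcal.stats import pearson


class TestCaGenerator:
    def test_silent_config_gives_flat_background(self):
        cfg = SynthConfig(noise_sd=0.0, spike_rate=0.0, bleach_rate=0.0, duration=10.0)
        kymo, truth = make_ca_kymograph(cfg, 0)
        assert np.allclose(kymo.intensity, cfg.background)
        assert truth.spikes == []

    def test_determinism(self):
        cfg = SynthConfig()
        k1, t1 = make_ca_kymograph(cfg, 42)
        k2, t2 = make_ca_kymograph(cfg, 42)
        assert np.array_equal(k1.intensity, k2.intensity)
        assert [e.onset_s for e in t1.spikes] == [e.onset_s for e in t2.spikes]

    def test_different_seeds_differ(self):
        cfg = SynthConfig()
        k1, _ = make_ca_kymograph(cfg, 1)
        k2, _ = make_ca_kymograph(cfg, 2)
        assert not np.array_equal(k1.intensity, k2.intensity)

    def test_poisson_spike_counts(self):
        # 500 replicates of an exponential renewal: mean count ≈ rate·T
        cfg = SynthConfig(duration=60.0, spike_rate=0.2, noise_sd=0.0)
        counts = [len(make_ca_kymograph(cfg, s)[1].spikes) for s in range(500)]
        expected = cfg.spike_rate * cfg.duration
        se = np.sqrt(expected / 500)
        assert abs(np.mean(counts) - expected) < 3 * se + 0.2

    def test_truth_metrics_consistent_with_event_list(self):
        cfg = SynthConfig()
        _, truth = make_ca_kymograph(cfg, 3)
        assert truth.summary.influx_intensity == pytest.approx(
            sum(e.area for e in truth.spikes) / cfg.duration
        )


class TestIFTGenerator:
    def test_no_trains_empty_truth(self):
        cfg = SynthConfig(anterograde_rate=0.0, retrograde_rate=0.0, noise_sd=0.0, duration=10.0)
        kymo, truth = make_ift_kymograph(cfg, 0)
        assert truth.trajectories == []
        assert np.allclose(kymo.intensity, cfg.background)

    def test_single_train_injection_matches_image(self):
        # noise-free single train: clean image total equals truth intensity
        cfg = SynthConfig(
            anterograde_rate=0.02, retrograde_rate=0.0, noise_sd=0.0, duration=30.0
        )
        kymo, truth = make_ift_kymograph(cfg, 3)
        assert len(truth.trajectories) == 1
        deposited = (kymo.intensity - cfg.background).sum()
        assert deposited == pytest.approx(truth.trajectories[0].intensities.sum())
        assert truth.summary.injection_intensity == pytest.approx(
            deposited / (kymo.length_um * cfg.duration)
        )

    def test_truth_summary_recomputable(self):
        cfg = SynthConfig()
        kymo, truth = make_ift_kymograph(cfg, 5)
        antero_total = sum(
            t.intensities.sum() for t in truth.trajectories if t.direction == ANTEROGRADE
        )
        assert truth.summary.injection_intensity == pytest.approx(
            antero_total / (kymo.length_um * cfg.duration)
        )

    def test_spike_reactivation_releases_pauses(self):
        cfg = SynthConfig(
            duration=60.0,
            pause_prob=1.0,
            reactivate_on_spike=True,
            spike_rate=0.05,
            retrograde_rate=0.5,
            anterograde_rate=0.0,
        )
        _, truth = make_ift_kymograph(cfg, 2)
        spikes = truth.spike_times
        assert spikes.size > 0
        for t in truth.trajectories:
            pos = t.positions
            stalls = np.where(np.diff(pos) == 0)[0]
            if stalls.size == 0:
                continue
            # resumption can only happen at a spike time
            resume_idx = stalls[-1] + 1
            if resume_idx < len(pos) - 1:
                t_resume = t.frames[resume_idx] * cfg.frame_interval
                assert np.any(spikes <= t_resume + cfg.frame_interval)

    def test_truncated_trains_flagged(self):
        cfg = SynthConfig(duration=20.0)
        _, truth = make_ift_kymograph(cfg, 4)
        truncated = [t for t in truth.trajectories if t.truncated]
        assert truncated, "a 20 s movie at these rates must cut some trains"
        last_frame = int(round(cfg.duration / cfg.frame_interval)) - 1
        for t in truncated:
            assert t.end_frame == last_frame


class TestDualGenerator:
    def test_zero_fraction_decouples_channels(self):
        cfg = SynthConfig(bleedthrough_fraction=0.0, noise_sd=0.0)
        g, m, truth = make_dual_kymograph(cfg, 1)
        assert np.allclose(g.intensity, truth.clean_ca)

    def test_mixing_algebra_is_exact(self):
        cfg = SynthConfig(bleedthrough_fraction=0.2, noise_sd=0.0)
        g, m, truth = make_dual_kymograph(cfg, 1)
        recovered = g.intensity - cfg.bleedthrough_fraction * m.intensity
        assert np.allclose(recovered, truth.clean_ca, atol=1e-10)

    def test_shared_spike_process(self):
        cfg = SynthConfig(pause_prob=1.0, reactivate_on_spike=True)
        _, _, truth = make_dual_kymograph(cfg, 9)
        onsets = {round(e.onset_s, 3) for e in truth.spikes}
        assert len(truth.spike_times) >= len(onsets) > 0


class TestLengthSeries:
    def test_noiseless_linear_is_perfectly_correlated(self):
        df = make_length_series(50, ("linear", 10.0, 2.0), 0.0, 0)
        rho, r2 = pearson(df["length_um"], df["metric"])
        assert rho == pytest.approx(1.0)

    def test_zero_slope_uncorrelated_over_replicates(self):
        rhos = [
            pearson(*make_length_series(100, ("linear", 10.0, 0.0), 3.0, s).T.values)[0]
            for s in range(50)
        ]
        assert abs(np.mean(rhos)) < 3.0 / np.sqrt(100 * 50)

    def test_correlation_recovered_within_fisher_interval(self):
        # slope/noise chosen for a moderate true correlation at n=272
        n = 272
        df = make_length_series(n, ("linear", 100.0, 5.0), 40.0, 12)
        rho, _ = pearson(df["length_um"], df["metric"])
        sd_L = (14.0 - 2.0) / np.sqrt(12.0)
        rho_true = 5.0 * sd_L / np.hypot(5.0 * sd_L, 40.0)
        z = np.arctanh(rho) - np.arctanh(rho_true)
        assert abs(z) < 3.0 / np.sqrt(n - 3)

    def test_decay_form(self):
        df = make_length_series(20, ("decay", 1.0, 10.0), 0.0, 0)
        assert np.allclose(df["metric"], 1.0 + 10.0 / df["length_um"])

    def test_bad_form_rejected(self):
        with pytest.raises(ValueError):
            make_length_series(10, ("quadratic", 1.0, 1.0), 0.0, 0)


class TestConfigValidation:
    def test_bleedthrough_range(self):
        with pytest.raises(ValueError):
            SynthConfig(bleedthrough_fraction=1.0)

    def test_negative_rate(self):
        with pytest.raises(ValueError):
            SynthConfig(spike_rate=-0.1)

    def test_geometry(self):
        cfg = SynthConfig(flagellum_length=12.0, pixel_size=0.16, frame_interval=0.05, duration=60.0)
        assert cfg.n_rows == 76
        assert cfg.n_frames == 1200
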