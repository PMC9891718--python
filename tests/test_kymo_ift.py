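import numpy as np
import pandas as pd
import pytest

from flagcal.core import ANTEROGRADE, PAUSED_MIXED, RETROGRADE, IFTTrajectory, Kymograph
from flagcal.synth import SynthConfig, make_ift_kymograph
from flagcal import io as fio, kymo_ift


def make_traj(track_id, frames, positions, intensity=10.0, direction=""):
    t = IFTTrajectory(
        track_id=track_id,
        points=np.column_stack([frames, positions]),
        intensities=np.full(len(frames), float(intensity)),
    )
    t.direction = direction or kymo_ift.classify_direction(t)
    return t


class TestTracing:
    def test_blank_image_gives_no_tracks(self):
        kymo = Kymograph(np.zeros((40, 200)))
        assert kymo_ift.trace_trajectories(kymo) == []

    def test_single_clean_train_velocity(self):
        cfg = SynthConfig(
            anterograde_rate=0.02, retrograde_rate=0.0, noise_sd=0.0, duration=30.0
        )
        kymo, truth = make_ift_kymograph(cfg, 3)
        trajs = kymo_ift.trace_trajectories(kymo)
        assert len(trajs) == 1
        assert trajs[0].direction == ANTEROGRADE
        assert trajs[0].velocity_um_s == pytest.approx(2.0, rel=0.03)

    def test_sparse_trains_high_recall_precision(self):
        # well-separated trains: essentially every train found, no phantoms
        cfg = SynthConfig(anterograde_rate=0.15, retrograde_rate=0.1, duration=60.0)
        hits = 0
        totals = 0
        traced_total = 0
        matched_traced = 0
        for seed in range(3):
            kymo, truth = make_ift_kymograph(cfg, seed)
            trajs = kymo_ift.trace_trajectories(kymo)

            def matches(tr, tt):
                f1, f2 = tr.frames.astype(int), tt.frames.astype(int)
                common, i1, i2 = np.intersect1d(f1, f2, return_indices=True)
                if len(common) < 4:
                    return False
                return np.mean(np.abs(tr.positions[i1] - tt.positions[i2])) < 2.0

            long_truth = [t for t in truth.trajectories if len(t.points) >= 10]
            totals += len(long_truth)
            hits += sum(1 for tt in long_truth if any(matches(tr, tt) for tr in trajs))
            traced_total += len(trajs)
            matched_traced += sum(
                1 for tr in trajs if any(matches(tr, tt) for tt in truth.trajectories)
            )
        assert hits / totals >= 0.95
        assert matched_traced / traced_total >= 0.95

    def test_injection_intensity_against_truth(self, ift_dataset):
        cfg, kymo, truth = ift_dataset
        trajs = kymo_ift.trace_trajectories(kymo)
        meas = kymo_ift.injection_intensity(trajs, kymo)
        assert meas == pytest.approx(truth.summary.injection_intensity, rel=0.10)


class TestImport:
    def test_round_trip_identity(self, tmp_path, ift_dataset):
        _, kymo, truth = ift_dataset
        path = tmp_path / "trajs.csv"
        fio.write_trajectories_csv(path, truth.trajectories)
        back = kymo_ift.import_trajectories(path)
        assert len(back) == len(truth.trajectories)
        for a, b in zip(truth.trajectories, back):
            assert np.allclose(a.points, b.points)
            assert np.allclose(a.intensities, b.intensities)
            assert a.direction == b.direction

    def test_malformed_frames_named(self, tmp_path):
        df = pd.DataFrame(
            {"track_id": [7, 7], "frame": [5, 5], "position_px": [1.0, 2.0], "intensity": [1, 1]}
        )
        p = tmp_path / "bad.csv"
        df.to_csv(p, index=False)
        with pytest.raises(ValueError, match="track 7"):
            kymo_ift.import_trajectories(p)

    def test_missing_columns_rejected(self, tmp_path):
        p = tmp_path / "cols.csv"
        pd.DataFrame({"track_id": [0], "frame": [0]}).to_csv(p, index=False)
        with pytest.raises(ValueError, match="position_px"):
            kymo_ift.import_trajectories(p)

    def test_imported_truth_reproduces_summary_exactly(self, tmp_path, ift_dataset):
        _, kymo, truth = ift_dataset
        path = tmp_path / "truth.csv"
        fio.write_trajectories_csv(path, truth.trajectories)
        imported = kymo_ift.import_trajectories(path)
        s = kymo_ift.summarize(kymo, imported, extrapolate_px=0.0)
        ts = truth.summary
        assert s.injection_intensity == pytest.approx(ts.injection_intensity, abs=1e-9)
        assert s.anterograde_frequency == pytest.approx(ts.anterograde_frequency, abs=1e-12)
        assert s.retrograde_frequency == pytest.approx(ts.retrograde_frequency, abs=1e-12)
        assert s.anterograde_velocity == pytest.approx(ts.anterograde_velocity, abs=1e-9)
        assert s.retrograde_velocity == pytest.approx(ts.retrograde_velocity, abs=1e-9)


class TestLinkAndDedupe:
    def test_gap_split_fragments_merge(self):
        a = make_traj(0, np.arange(0, 20), 2.0 + 0.6 * np.arange(0, 20))
        b = make_traj(1, np.arange(23, 40), 2.0 + 0.6 * np.arange(23, 40))
        out = kymo_ift.link_and_dedupe([a, b])
        assert len(out) == 1
        assert len(out[0].points) == 37

    def test_duplicate_track_removed(self):
        a = make_traj(0, np.arange(0, 30), 1.0 + 0.5 * np.arange(30), intensity=10)
        b = make_traj(1, np.arange(0, 30), 1.0 + 0.5 * np.arange(30), intensity=8)
        out = kymo_ift.link_and_dedupe([a, b])
        assert len(out) == 1
        assert out[0].intensities[0] == 10  # higher total intensity survives

    def test_parallel_distinct_tracks_kept(self):
        a = make_traj(0, np.arange(0, 30), 1.0 + 0.5 * np.arange(30))
        b = make_traj(1, np.arange(0, 30), 11.0 + 0.5 * np.arange(30))
        assert len(kymo_ift.link_and_dedupe([a, b])) == 2

    def test_idempotent_and_never_grows(self):
        rng = np.random.default_rng(0)
        trajs = [
            make_traj(i, np.arange(s, s + 15), rng.uniform(0, 30) + 0.6 * np.arange(15))
            for i, s in enumerate(rng.integers(0, 100, 12))
        ]
        once = kymo_ift.link_and_dedupe(trajs)
        twice = kymo_ift.link_and_dedupe(once)
        assert len(twice) == len(once) <= len(trajs)
        for a, b in zip(once, twice):
            assert np.allclose(a.points, b.points)


class TestMetrics:
    def test_empty_inputs(self):
        kymo = Kymograph(np.zeros((30, 100)))
        assert kymo_ift.injection_intensity([], kymo) == 0.0
        assert kymo_ift.train_frequency([], 10.0, ANTEROGRADE) == 0.0
        assert kymo_ift.returning_intensity([], (0, 5), 0.05) == 0.0

    def test_single_train_arithmetic(self):
        # n pixels of intensity I on an L µm, T s kymograph
        kymo = Kymograph(np.zeros((31, 100)), pixel_size=0.2, frame_interval=0.1)
        tr = make_traj(0, np.arange(0, 25), 1.0 + np.arange(25), intensity=4.0)
        expected = 25 * 4.0 / (kymo.length_um * kymo.duration_s)
        assert kymo_ift.injection_intensity([tr], kymo) == pytest.approx(expected)

    def test_returning_intensity_sums_mean_intensities(self):
        # two retrograde trains reaching the base inside the window
        t1 = make_traj(0, np.arange(0, 20), 20.0 - np.arange(20), intensity=10.0)
        t2 = make_traj(1, np.arange(30, 50), 20.0 - np.arange(20), intensity=5.0)
        total = kymo_ift.returning_intensity([t1, t2], (0.0, 10.0), 0.05)
        assert total == pytest.approx(15.0)
        assert kymo_ift.returning_intensity([t1, t2], (100.0, 110.0), 0.05) == 0.0

    def test_paused_mixed_excluded_from_frequency(self):
        stalled = make_traj(0, np.arange(0, 30), np.full(30, 1.0))
        assert stalled.direction == PAUSED_MIXED
        assert kymo_ift.train_frequency([stalled], 10.0, ANTEROGRADE) == 0.0

    def test_velocity_with_pause_excluded(self):
        # 1 px/frame motion with a 20-frame stall in the middle
        pos = np.concatenate([np.arange(20.0), np.full(20, 19.0), 19.0 + np.arange(1, 21)])
        tr = make_traj(0, np.arange(len(pos)), pos)
        v = kymo_ift.train_velocity(tr, 0.16, 0.05, exclude_pauses=True)
        assert v == pytest.approx(1.0 * 0.16 / 0.05, rel=0.05)
        v_all = kymo_ift.train_velocity(tr, 0.16, 0.05, exclude_pauses=False)
        assert v_all < v

    def test_time_reversal_of_retrograde_leaves_injection(self, ift_dataset):
        _, kymo, truth = ift_dataset
        inj = kymo_ift.injection_intensity(truth.trajectories, kymo)
        flipped = [
            t
            if t.direction == ANTEROGRADE
            else IFTTrajectory(
                track_id=t.track_id,
                points=np.column_stack(
                    [t.points[::-1, 0].max() - t.points[::-1, 0] + t.points[:, 0].min(),
                     t.points[::-1, 1]]
                ),
                intensities=t.intensities[::-1],
            )
            for t in truth.trajectories
        ]
        for f, o in zip(flipped, truth.trajectories):
            f.direction = o.direction
        assert kymo_ift.injection_intensity(flipped, kymo) == pytest.approx(inj)

    def test_gain_linearity_of_injection(self, ift_dataset):
        _, kymo, _ = ift_dataset
        trajs = kymo_ift.trace_trajectories(kymo)
        inj1 = kymo_ift.injection_intensity(trajs, kymo)
        bright = kymo.with_intensity(kymo.intensity * 2.0)
        trajs2 = kymo_ift.trace_trajectories(bright)
        inj2 = kymo_ift.injection_intensity(trajs2, bright)
        assert inj2 == pytest.approx(2.0 * inj1, rel=0.05)


class TestBackground:
    def test_no_trajectories_gives_global_mean(self):
        img = np.random.default_rng(0).normal(30.0, 2.0, (40, 200))
        kymo = Kymograph(img)
        assert kymo_ift.background_intensity(kymo, []) == pytest.approx(img.mean())

    def test_bright_tracks_masked_out(self):
        rng = np.random.default_rng(1)
        img = rng.normal(30.0, 2.0, (40, 200))
        tr = make_traj(0, np.arange(0, 200), np.full(200, 20.0))
        img[19:22, :] += 500.0
        kymo = Kymograph(img)
        bg = kymo_ift.background_intensity(kymo, [tr], mask_halfwidth_px=3)
        assert bg == pytest.approx(30.0, abs=3 * 2.0 / np.sqrt(img.size))

    def test_fully_masked_image_raises(self):
        kymo = Kymograph(np.zeros((5, 50)))
        trajs = [make_traj(i, np.arange(0, 50), np.full(50, float(i))) for i in range(5)]
        with pytest.raises(ValueError, match="no background"):
            kymo_ift.background_intensity(kymo, trajs, mask_halfwidth_px=3)
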