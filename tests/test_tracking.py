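"""Blob detection, LAP linking with gap closing, track filtering and
migration metrics, validated against planted walkers."""

import numpy as np
import pandas as pd
import pytest

from lamelloscope import synthetic as syn
from lamelloscope.tracking import (detect_blobs_log, displacement_speed,
                                   filter_tracks, link_tracks,
                                   migration_metrics, read_trackmate_csv,
                                   to_trackmate_csv)


def _partition_matches_truth(linked, truth_df):
    """Every recovered track maps 1:1 onto a planted track."""
    merged = linked.merge(truth_df, on="frame", suffixes=("", "_t"))
    same = merged[np.isclose(merged.x_um, merged.x_um_t)
                  & np.isclose(merged.y_um, merged.y_um_t)]
    if len(same) < len(linked):
        return False
    return (same.groupby("track_id")["true_track_id"].nunique().max() == 1
            and same.groupby("true_track_id")["track_id"].nunique().max() == 1)


class TestDetectBlobsLog:
    def _blob_image(self, centers, sigma=6.0, shape=(120, 120)):
        rr, cc = np.mgrid[0:shape[0], 0:shape[1]]
        img = np.zeros(shape)
        for r0, c0 in centers:
            img += 100 * np.exp(-((rr - r0) ** 2 + (cc - c0) ** 2)
                                / (2 * sigma ** 2))
        return img

    def test_single_blob_localised_within_one_pixel(self):
        img = self._blob_image([(40.0, 70.0)])
        det = detect_blobs_log(img, pixel_size_um=1.5, diameter_um=25)
        assert len(det) == 1
        assert det.loc[0, "x_um"] == pytest.approx(70 * 1.5, abs=1.5)
        assert det.loc[0, "y_um"] == pytest.approx(40 * 1.5, abs=1.5)

    def test_blank_image_gives_no_detections(self):
        det = detect_blobs_log(np.zeros((60, 60)), pixel_size_um=1.5)
        assert det.empty

    def test_two_separated_blobs(self):
        img = self._blob_image([(30, 30), (90, 90)])
        det = detect_blobs_log(img, pixel_size_um=1.5, diameter_um=25)
        assert len(det) == 2

    def test_quality_threshold_suppresses_weak_blobs(self):
        img = self._blob_image([(30, 30)]) + 0.02 * self._blob_image([(90, 90)])
        det = detect_blobs_log(img, pixel_size_um=1.5, diameter_um=25,
                               quality_threshold=0.08)
        assert len(det) == 1

    def test_tiny_diameter_rejected(self):
        with pytest.raises(ValueError):
            detect_blobs_log(np.zeros((20, 20)), pixel_size_um=10.0,
                             diameter_um=25)


class TestLinkTracks:
    def test_dropout_free_walkers_recover_exact_partition(self):
        for seed in range(3):
            det, truth = syn.simulate_tracks(n_cells=8, n_frames=15,
                                             speed_um_min=0.6,
                                             persistence=0.6, seed=seed)
            linked = link_tracks(det)
            assert linked["track_id"].nunique() == 8
            assert _partition_matches_truth(linked, truth.true_tracks)

    def test_single_frame_dropout_bridged_by_gap_closing(self):
        det, truth = syn.simulate_tracks(n_cells=1, n_frames=12, seed=0)
        det = det[det["frame"] != 5].reset_index(drop=True)
        linked = link_tracks(det)
        assert linked["track_id"].nunique() == 1
        frames = linked["frame"].tolist()
        assert 4 in frames and 6 in frames

    def test_gap_longer_than_max_not_closed(self):
        det, _ = syn.simulate_tracks(n_cells=1, n_frames=12, seed=0)
        det = det[~det["frame"].isin([4, 5, 6, 7])].reset_index(drop=True)
        linked = link_tracks(det, max_frame_gap=3)
        assert linked["track_id"].nunique() == 2

    def test_distant_detections_not_linked(self):
        det = pd.DataFrame({"frame": [0, 1], "x_um": [0.0, 60.0],
                            "y_um": [0.0, 0.0], "quality": [1.0, 1.0]})
        linked = link_tracks(det, max_link_um=50.0)
        assert linked["track_id"].nunique() == 2

    def test_invariant_to_detection_order_within_frames(self):
        det, truth = syn.simulate_tracks(n_cells=6, n_frames=10, seed=2)
        shuffled = det.sample(frac=1.0, random_state=7).reset_index(drop=True)
        a = link_tracks(det).sort_values(["frame", "x_um"])
        b = link_tracks(shuffled).sort_values(["frame", "x_um"])
        # same grouping: compare partition signatures
        sig_a = a.groupby("track_id")["x_um"].apply(tuple).sort_values()
        sig_b = b.groupby("track_id")["x_um"].apply(tuple).sort_values()
        assert sorted(sig_a) == sorted(sig_b)

    def test_empty_input_gives_empty_table(self):
        out = link_tracks(pd.DataFrame(columns=["frame", "x_um", "y_um"]))
        assert out.empty and "track_id" in out.columns


class TestFilterTracks:
    def test_planted_mixture_filtered_exactly(self):
        # 10 long tracks pass, 5 short ones fail the 60-min rule
        frames_long = 11   # 10 intervals x 12 min = 120 min
        frames_short = 4   # 3 intervals x 12 min = 36 min
        rows = []
        for tid in range(15):
            n = frames_long if tid < 10 else frames_short
            for f in range(n):
                rows.append({"track_id": tid, "frame": f,
                             "x_um": tid * 100.0 + f * 2.0, "y_um": 0.0})
        tracks = pd.DataFrame(rows)
        kept = filter_tracks(tracks, frame_interval_s=720.0,
                             min_duration_min=60.0, min_span_um=18.0)
        assert kept["track_id"].nunique() == 10

    def test_duration_just_below_cutoff_removed(self):
        tracks = pd.DataFrame({"track_id": 0, "frame": range(6),
                               "x_um": np.arange(6) * 5.0, "y_um": 0.0})
        # 5 intervals x 708 s = 59 min
        kept = filter_tracks(tracks, frame_interval_s=708.0)
        assert kept.empty

    def test_span_metric_switch(self):
        # closed loop: long path, zero displacement
        theta = np.linspace(0, 2 * np.pi, 13)
        tracks = pd.DataFrame({"track_id": 0, "frame": range(13),
                               "x_um": 10 * np.cos(theta),
                               "y_um": 10 * np.sin(theta)})
        by_path = filter_tracks(tracks, 720.0, min_duration_min=60,
                                min_span_um=18, span_metric="path")
        by_disp = filter_tracks(tracks, 720.0, min_duration_min=60,
                                min_span_um=18, span_metric="displacement")
        assert not by_path.empty and by_disp.empty


class TestMigrationMetrics:
    def test_straight_track_di_one(self):
        track = pd.DataFrame({"frame": range(5), "x_um": np.arange(5) * 3.0,
                              "y_um": 0.0})
        _, di = migration_metrics(track, 60.0)
        assert di == pytest.approx(1.0)

    def test_closed_loop_di_zero(self):
        theta = np.linspace(0, 2 * np.pi, 9)
        track = pd.DataFrame({"frame": range(9), "x_um": np.cos(theta),
                              "y_um": np.sin(theta)})
        _, di = migration_metrics(track, 60.0)
        assert di == pytest.approx(0.0, abs=1e-12)

    def test_worked_right_triangle(self):
        track = pd.DataFrame({"frame": [0, 1, 2], "x_um": [0.0, 3.0, 3.0],
                              "y_um": [0.0, 0.0, 4.0]})
        speed, di = migration_metrics(track, 60.0)
        assert di == pytest.approx(5.0 / 7.0)
        assert speed == pytest.approx(7.0 / 2.0)

    def test_invariant_to_rigid_motion(self, rng):
        p = rng.uniform(0, 50, (8, 2))
        track = pd.DataFrame({"frame": range(8), "x_um": p[:, 0],
                              "y_um": p[:, 1]})
        angle = 0.7
        rot = np.array([[np.cos(angle), -np.sin(angle)],
                        [np.sin(angle), np.cos(angle)]])
        q = p @ rot.T + [120.0, -40.0]
        moved = pd.DataFrame({"frame": range(8), "x_um": q[:, 0],
                              "y_um": q[:, 1]})
        np.testing.assert_allclose(migration_metrics(track, 60.0),
                                   migration_metrics(moved, 60.0))

    def test_displacement_speed_example(self):
        # 30 µm net over 2 hr -> 15 µm/hr
        track = pd.DataFrame({"frame": [0, 2], "x_um": [0.0, 30.0],
                              "y_um": 0.0})
        assert displacement_speed(track, 3600.0) == pytest.approx(15.0)

    def test_displacement_speed_closed_loop_zero(self):
        track = pd.DataFrame({"frame": [0, 1, 2], "x_um": [0.0, 10.0, 0.0],
                              "y_um": 0.0})
        assert displacement_speed(track, 3600.0) == 0.0

    def test_planted_straight_walker_speed_recovered(self):
        det, truth = syn.simulate_tracks(n_cells=1, n_frames=10,
                                         speed_um_min=0.8, persistence=1.0,
                                         frame_interval_s=600.0, seed=1)
        linked = link_tracks(det)
        speed, di = migration_metrics(linked, 600.0)
        assert speed == pytest.approx(0.8)
        assert di == pytest.approx(1.0)

    def test_single_point_track_rejected(self):
        with pytest.raises(ValueError):
            migration_metrics(pd.DataFrame({"frame": [0], "x_um": [0.0],
                                            "y_um": [0.0]}), 60.0)


class TestTrackmateIo:
    def test_column_round_trip(self, tmp_path):
        tracks = pd.DataFrame({"track_id": [0, 0], "frame": [0, 1],
                               "x_um": [1.0, 2.0], "y_um": [3.0, 4.0]})
        to_trackmate_csv(tracks, tmp_path / "t.csv")
        header = (tmp_path / "t.csv").read_text().splitlines()[0]
        assert header == "TRACK_ID,FRAME,POSITION_X,POSITION_Y"
        back = read_trackmate_csv(tmp_path / "t.csv")
        pd.testing.assert_frame_equal(back, tracks)
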