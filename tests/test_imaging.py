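"""Detection, linking, segmentation, feature and classification checks."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from smtpop.imaging import (
    DetectionParams,
    SegmentationParams,
    assign_trajectories_to_cells,
    classify_marker,
    default_max_radius,
    detect_spots,
    link_localizations,
    marker_positive_fraction,
    nucleus_features,
    segment_nuclei,
    two_nearest_distances,
)


def render_spot(shape, cx, cy, sigma=1.0, amplitude=1000.0):
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    return amplitude * np.exp(-((xx - cx) ** 2 + (yy - cy) ** 2) / (2 * sigma**2))


class TestDetectSpots:
    def test_blank_frame_empty(self):
        assert detect_spots(np.zeros((64, 64))).empty

    def test_non_2d_rejected(self):
        with pytest.raises(ValueError, match="2D"):
            detect_spots(np.zeros((4, 4, 4)))

    @pytest.mark.parametrize("cx,cy", [(20.3, 31.7), (40.0, 12.5)])
    def test_subpixel_accuracy(self, cx, cy):
        img = render_spot((64, 64), cx, cy)
        spots = detect_spots(img, DetectionParams(threshold=1.0))
        assert len(spots) == 1
        assert abs(spots["x_px"].iloc[0] - cx) < 0.1
        assert abs(spots["y_px"].iloc[0] - cy) < 0.1

    def test_two_separated_spots(self):
        img = render_spot((64, 64), 20, 20) + render_spot((64, 64), 29, 20)
        spots = detect_spots(img, DetectionParams(threshold=1.0))
        assert len(spots) == 2


class TestLinking:
    def locs(self, rows):
        return pd.DataFrame(rows, columns=["frame", "x_um", "y_um"])

    def test_single_molecule_single_trajectory(self):
        locs = self.locs([(f, 1.0 + 0.01 * f, 2.0) for f in range(6)])
        linked = link_localizations(locs, max_radius=0.1)
        assert linked["trajectory_id"].nunique() == 1

    def test_two_far_molecules_no_mislinks(self):
        a = [(f, 0.0 + 0.01 * f, 0.0) for f in range(5)]
        b = [(f, 10.0 - 0.01 * f, 10.0) for f in range(5)]
        linked = link_localizations(self.locs(a + b), max_radius=0.5)
        groups = linked.groupby("trajectory_id")["x_um"].apply(set)
        assert len(groups) == 2
        # each trajectory contains only one molecule's positions
        assert all((min(g) < 1) == (max(g) < 1) for g in groups)

    def test_termination_without_neighbor(self):
        locs = self.locs([(0, 0.0, 0.0), (1, 0.01, 0.0), (2, 5.0, 0.0)])
        linked = link_localizations(locs, max_radius=0.1)
        assert linked["trajectory_id"].nunique() == 2

    def test_gap_closing(self):
        locs = self.locs([(0, 0.0, 0.0), (2, 0.02, 0.0)])
        assert link_localizations(locs, max_radius=0.1, max_gap=0)["trajectory_id"].nunique() == 2
        assert link_localizations(locs, max_radius=0.1, max_gap=1)["trajectory_id"].nunique() == 1

    def test_negative_radius_rejected(self):
        with pytest.raises(ValueError):
            link_localizations(self.locs([(0, 0, 0)]), max_radius=-1)

    def test_conservation_each_loc_once_frames_increasing(self):
        rng = np.random.default_rng(0)
        rows = [(f, rng.uniform(0, 20), rng.uniform(0, 20)) for f in range(10) for _ in range(15)]
        linked = link_localizations(self.locs(rows), max_radius=1.0)
        assert len(linked) == len(rows)  # every localization appears exactly once
        for _, sub in linked.groupby("trajectory_id"):
            assert np.all(np.diff(np.sort(sub["frame"].values)) > 0)

    def test_default_radius_scale(self):
        # 2.45 * sqrt(4 D dt)
        assert np.isclose(default_max_radius(5.0, 0.01), 2.45 * np.sqrt(0.2))


class TestSegmentation:
    def disk_image(self, centers, radii, shape=(200, 200), value=1000.0):
        yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
        img = np.zeros(shape)
        for (cy, cx), r in zip(centers, radii):
            img[((xx - cx) ** 2 + (yy - cy) ** 2) <= r**2] = value
        return img

    def test_blank_image_zero_nuclei(self):
        mask = segment_nuclei(np.zeros((64, 64)))
        assert mask.max() == 0

    def test_five_disks_areas(self):
        centers = [(40, 40), (40, 140), (140, 40), (140, 140), (100, 95)]
        radii = [15, 18, 20, 16, 17]
        mask = segment_nuclei(self.disk_image(centers, radii))
        labels = np.unique(mask)
        assert len(labels) == 6  # background + 5
        feats = nucleus_features(mask, pixel_size=1.0)
        areas = np.sort(feats["nuclear_area"].values)
        expected = np.sort([np.pi * r**2 for r in radii])
        assert np.all(np.abs(areas - expected) / expected < 0.05)

    def test_touching_disks_split(self):
        mask = segment_nuclei(
            self.disk_image([(60, 50), (60, 82)], [20, 20], shape=(120, 140)),
            SegmentationParams(watershed_footprint_px=10),
        )
        assert mask.max() == 2


class TestFeatures:
    def mask_from_points(self, pts, shape=(100, 100)):
        mask = np.zeros(shape, dtype=np.int32)
        for i, (y, x) in enumerate(pts, 1):
            mask[y, x] = i
        return mask

    def test_collinear_three_points(self):
        feats = nucleus_features(self.mask_from_points([(5, 0), (5, 10), (5, 20)]), pixel_size=0.1)
        # spacing 1.0 um: middle = 1.0, ends = 1.5
        d = feats.sort_values("cell_id")["two_nearest_dist"].values
        assert np.allclose(d, [1.5, 1.0, 1.5])

    def test_unit_square(self):
        feats = nucleus_features(
            self.mask_from_points([(0, 0), (0, 10), (10, 0), (10, 10)]), pixel_size=0.1
        )
        assert np.allclose(feats["two_nearest_dist"].values, 1.0)

    def test_random_layouts_match_bruteforce_exactly(self):
        rng = np.random.default_rng(1)
        pts = rng.uniform(0, 50, size=(50, 2))
        package = two_nearest_distances(pts)
        for i in range(50):
            d = np.sort([np.hypot(*(pts[i] - pts[j])) for j in range(50) if j != i])
            assert abs(package[i] - (d[0] + d[1]) / 2) < 1e-9

    def test_fewer_than_three_nuclei_undefined(self):
        feats = nucleus_features(self.mask_from_points([(5, 5), (20, 20)]), pixel_size=1.0)
        assert feats["two_nearest_dist"].isna().all()

    def test_mean_channel_intensity(self):
        mask = np.zeros((10, 10), dtype=np.int32)
        mask[2:4, 2:4] = 1
        channel = np.full((10, 10), 3.0)
        channel[2:4, 2:4] = 11.0
        feats = nucleus_features(mask, 1.0, {"marker_intensity": channel})
        assert feats["marker_intensity"].iloc[0] == 11.0


class TestMarkerClassification:
    def records(self, intensities, fov=0):
        return pd.DataFrame(
            {"cell_id": np.arange(len(intensities)), "fov_id": fov, "marker_intensity": intensities}
        )

    def test_fixed_threshold_all_positive(self):
        out = classify_marker(self.records([10.0, 20.0, 30.0]), "fixed_threshold", threshold=5.0)
        assert (out["marker_class"] == "positive").all()

    def test_otsu_recovers_clean_bimodal(self):
        rng = np.random.default_rng(2)
        n = 200
        truth = rng.random(n) < 0.4
        intensities = np.where(truth, rng.normal(1000, 50, n), rng.normal(100, 50, n))
        out = classify_marker(self.records(intensities), "otsu_per_fov")
        assert ((out["marker_class"] == "positive") == truth).all()

    def test_constant_intensities_unassigned(self):
        out = classify_marker(self.records([5.0, 5.0, 5.0]), "otsu_per_fov")
        assert (out["marker_class"] == "unassigned").all()

    def test_positive_fraction_simple(self):
        rec = self.records([1, 1, 1, 0.0])
        rec["marker_class"] = ["positive", "positive", "positive", "negative"]
        assert marker_positive_fraction(rec).iloc[0] == 75.0

    def test_unclassified_group_absent(self):
        rec = self.records([1.0, 2.0])
        rec["marker_class"] = "unassigned"
        assert len(marker_positive_fraction(rec)) == 0

    def test_fraction_within_binomial_bounds(self):
        rng = np.random.default_rng(3)
        rates = []
        for fov in range(20):
            rec = self.records(np.zeros(30), fov=fov)
            rec["marker_class"] = np.where(rng.random(30) < 0.5, "positive", "negative")
            rates.append(marker_positive_fraction(rec).iloc[0])
        lo, hi = stats.binom.ppf([0.005, 0.995], 600, 0.5) / 600 * 100
        assert lo <= np.mean(rates) <= hi


class TestTrajectoryAssignment:
    def test_majority_rule_and_tie_discard(self):
        mask = np.zeros((20, 20), dtype=np.int32)
        mask[:, :10] = 1
        mask[:, 10:] = 2
        traj = pd.DataFrame(
            {
                "fov_id": 0,
                "cell_id": -1,
                "trajectory_id": [0, 0, 0, 1, 1],
                "frame": [0, 1, 2, 0, 1],
                "x_um": [2.0, 3.0, 12.0, 5.0, 15.0],  # traj 0: majority label 1; traj 1: tie
                "y_um": 5.0,
                "class": "DR",
            }
        )
        out, n_discarded = assign_trajectories_to_cells(traj, mask, pixel_size=1.0)
        assert n_discarded == 1
        assert set(out["trajectory_id"]) == {0}
        assert (out["cell_id"] == 1).all()
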