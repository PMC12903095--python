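"""Generator-level checks: Brownian statistics, truncation, populations, PAPA labels."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from smtpop import (
    AcquisitionParams,
    CellSpec,
    IlluminationSchedule,
    MotionState,
    PapaDesign,
    PopulationConfig,
    assign_papa_classes,
    render_frames,
    simulate_cell_trajectories,
    simulate_papa_population,
    simulate_population,
    two_state_mixture,
)
from smtpop.synthdata import MarkerModel


def jumps_of(traj):
    df = traj.sort_values(["trajectory_id", "frame"])
    same = df["trajectory_id"].values[1:] == df["trajectory_id"].values[:-1]
    consec = np.diff(df["frame"].values) == 1
    keep = same & consec
    dx = np.diff(df["x_um"].values)[keep]
    dy = np.diff(df["y_um"].values)[keep]
    return np.hypot(dx, dy)


class TestValidation:
    def test_negative_d_rejected(self):
        with pytest.raises(ValueError, match="D"):
            MotionState("bad", -1.0, 1.0)

    def test_unnormalized_weights_rejected(self, acq):
        spec = CellSpec(cell_id=0, states=[MotionState("a", 1.0, 0.5)], n_trajectories=10)
        with pytest.raises(ValueError, match="sum to 1"):
            simulate_cell_trajectories(spec, acq, seed=0)

    def test_bad_radius_rejected(self, acq):
        spec = CellSpec(cell_id=0, states=two_state_mixture(0.5), n_trajectories=10, nucleus_radius=0.0)
        with pytest.raises(ValueError, match="nucleus_radius"):
            simulate_cell_trajectories(spec, acq, seed=0)


class TestSingleCell:
    def test_immobile_zero_error_gives_zero_jumps(self, single_state_spec):
        acq = AcquisitionParams(sigma_loc=1e-12, mean_track_len=10)
        traj, _ = simulate_cell_trajectories(single_state_spec(0.0, 200), acq, seed=1)
        assert np.allclose(jumps_of(traj), 0.0, atol=1e-9)

    def test_no_bleaching_fixed_movie_length(self, single_state_spec, acq):
        traj, _ = simulate_cell_trajectories(
            single_state_spec(0.0, 50), acq, seed=1, bleaching=False,
            axial_truncation=False, fixed_length=12,
        )
        assert (traj.groupby("trajectory_id").size() == 12).all()

    def test_static_molecule_mean_jump_is_sigma_sqrt_pi(self, single_state_spec):
        # per-axis displacement variance 2*sigma^2 -> Rayleigh mean sigma*sqrt(pi)
        sigma = 0.035
        acq = AcquisitionParams(sigma_loc=sigma, mean_track_len=10)
        traj, _ = simulate_cell_trajectories(
            single_state_spec(0.0, 3000), acq, seed=3, bleaching=False,
            axial_truncation=False, fixed_length=5,
        )
        r = jumps_of(traj)
        assert r.size >= 10_000
        expected = sigma * np.sqrt(np.pi)
        se = r.std() / np.sqrt(r.size)
        assert abs(r.mean() - expected) < 3 * se

    def test_deterministic_given_seed(self, single_state_spec, acq):
        t1, g1 = simulate_cell_trajectories(single_state_spec(1.0, 100), acq, seed=7)
        t2, g2 = simulate_cell_trajectories(single_state_spec(1.0, 100), acq, seed=7)
        pd.testing.assert_frame_equal(t1, t2)
        pd.testing.assert_frame_equal(g1, g2)

    def test_state_mixture_time_fractions(self, acq):
        # without axial truncation, time in each state converges to its weight
        spec = CellSpec(
            cell_id=0,
            states=[MotionState("bound", 0.01, 0.3), MotionState("free", 5.0, 0.7)],
            n_trajectories=12_000,
            nucleus_radius=50.0,
            nucleus_center=(50.0, 50.0),
        )
        acq10 = AcquisitionParams(mean_track_len=10)
        traj, truth = simulate_cell_trajectories(spec, acq10, seed=4, axial_truncation=False)
        merged = traj.merge(truth, on=["cell_id", "trajectory_id"])
        assert len(merged) > 1e5
        frac_bound = (merged["state"] == "bound").mean()
        assert abs(frac_bound - 0.3) < 0.01

    def test_axial_truncation_shortens_fast_states(self, single_state_spec, acq):
        means = []
        for D in (0.01, 1.0, 10.0):
            traj, _ = simulate_cell_trajectories(single_state_spec(D, 3000), acq, seed=5)
            means.append(traj.groupby("trajectory_id").size().mean())
        assert means[0] > means[1] > means[2]

    @pytest.mark.parametrize("D", [0.5])
    def test_jump_distribution_matches_rayleigh(self, single_state_spec, D):
        # squared radial displacement ~ Exp(mean 4*(D dt + sigma^2))
        acq = AcquisitionParams()
        scale = np.sqrt(2 * (D * acq.dt + acq.sigma_loc**2))
        passes = 0
        for seed in range(5):
            traj, _ = simulate_cell_trajectories(
                single_state_spec(D, 4000), acq, seed=seed, axial_truncation=False,
                bleaching=False, fixed_length=4,
            )
            r = jumps_of(traj)
            assert r.size >= 10_000
            p = stats.kstest(r[:10_000], "rayleigh", args=(0, scale)).pvalue
            passes += p > 0.01
        assert passes >= 4


class TestPopulation:
    def test_identical_mixes_give_identical_truth(self, acq):
        config = PopulationConfig(n_cells=10, n_trajectories=20, fb_mean=0.5, fb_sd=0.0)
        ds = simulate_population(config, acq, seed=0)
        assert ds.ground_truth.cells["true_fb"].nunique() == 1

    def test_population_fb_mean_close_to_configured(self, acq):
        config = PopulationConfig(n_cells=150, n_trajectories=0, fb_mean=0.4)
        ds = simulate_population(config, acq, seed=1)
        assert abs(ds.ground_truth.cells["true_fb"].mean() - 0.4) < 0.03

    def test_marker_class_counts_within_binomial_bounds(self, acq):
        config = PopulationConfig(
            n_cells=200, n_trajectories=0, use_marker=True,
            marker=MarkerModel(positive_fraction=0.25),
        )
        ds = simulate_population(config, acq, seed=2)
        n_pos = (ds.ground_truth.cells["marker_class"] == "positive").sum()
        lo, hi = stats.binom.ppf([0.005, 0.995], 200, 0.25)
        assert lo <= n_pos <= hi

    def test_empty_population_is_explicit(self, acq):
        ds = simulate_population(PopulationConfig(n_cells=0), acq, seed=0)
        assert len(ds.trajectories) == 0 and len(ds.cells) == 0

    def test_dataset_determinism(self, acq):
        config = PopulationConfig(n_cells=5, n_trajectories=50)
        d1 = simulate_population(config, acq, seed=9)
        d2 = simulate_population(config, acq, seed=9)
        pd.testing.assert_frame_equal(d1.trajectories, d2.trajectories)
        assert d1.trajectories.to_csv() == d2.trajectories.to_csv()


class TestPapaAssignment:
    def make_dataset(self, acq, n_cells=30, n_traj=200, design=None, seed=0):
        design = design or PapaDesign(enrichment=1.0)
        schedule = IlluminationSchedule.alternating(n_cycles=200)
        config = PopulationConfig(n_cells=n_cells, n_trajectories=n_traj)
        return simulate_papa_population(config, design, schedule, acq, seed), schedule

    def truth_fb(self, ds, cls, design):
        t = ds.ground_truth.trajectories
        sub = t[t["class"] == cls]
        return np.where(sub["D"] < 0.15, 1.0, 0.0).mean()

    def test_null_enrichment_gives_equal_class_mixtures(self, acq):
        design = PapaDesign(enrichment=1.0, oligomer_fb=0.8, monomer_fb=0.3)
        ds, _ = self.make_dataset(acq, n_cells=40, n_traj=300, design=design, seed=1)
        fb_dr = self.truth_fb(ds, "DR", design)
        fb_papa = self.truth_fb(ds, "PAPA", design)
        n = len(ds.ground_truth.trajectories)
        assert abs(fb_dr - fb_papa) < 4 / np.sqrt(n)  # Monte-Carlo error margin

    def test_extreme_enrichment_selects_oligomers(self, acq):
        design = PapaDesign(enrichment=1e9, oligomer_fb=1.0, monomer_fb=0.3,
                            oligomer_fraction=0.5, papa_share=0.4)
        ds, _ = self.make_dataset(acq, n_cells=20, n_traj=200, design=design, seed=2)
        assert self.truth_fb(ds, "PAPA", design) > 0.97

    def test_enrichment_three_matches_mixture_arithmetic(self, acq):
        # closed form: PAPA-class FB = (f e b_o + (1-f) b_m) / (f e + 1 - f),
        # checked on a lossless hand-built dataset (no track-length selection)
        import smtpop.synthdata as sd

        f, e, b_o, b_m = 0.3, 3.0, 0.8, 0.3
        n = 20_000
        rng = np.random.default_rng(33)
        oligo = rng.random(n) < f
        bound = np.where(oligo, rng.random(n) < b_o, rng.random(n) < b_m)
        truth = pd.DataFrame(
            {"cell_id": 0, "trajectory_id": np.arange(n),
             "D": np.where(bound, 0.01, 5.0), "state": np.where(bound, "bound", "free"),
             "oligomer": oligo, "class": "DR"}
        )
        traj = pd.DataFrame(
            {"fov_id": 0, "cell_id": 0,
             "trajectory_id": np.repeat(np.arange(n), 2),
             "frame": np.tile([0, 1], n),
             "x_um": 1.0, "y_um": 1.0, "class": "DR"}
        )
        ds = sd.SyntheticDataset(
            trajectories=traj, cells=pd.DataFrame({"cell_id": [0]}),
            ground_truth=sd.GroundTruth(cells=pd.DataFrame(), trajectories=truth),
            acq=acq,
        )
        schedule = IlluminationSchedule.alternating(n_cycles=50)
        out = assign_papa_classes(ds, schedule, enrichment=e, nonspecific_rate=0.0, seed=7)
        t = out.ground_truth.trajectories
        papa = t[t["class"] == "PAPA"]
        f_hat = t["oligomer"].mean()
        b_o_hat = np.where(t.loc[t["oligomer"], "D"] < 0.15, 1, 0).mean()
        b_m_hat = np.where(t.loc[~t["oligomer"], "D"] < 0.15, 1, 0).mean()
        expected = (f_hat * e * b_o_hat + (1 - f_hat) * b_m_hat) / (f_hat * e + 1 - f_hat)
        realized = np.where(papa["D"] < 0.15, 1.0, 0.0).mean()
        se = np.sqrt(expected * (1 - expected) / len(papa))
        assert abs(realized - expected) < 3 * se

    def test_every_trajectory_gets_one_class(self, acq):
        ds, _ = self.make_dataset(acq, seed=4)
        assert set(ds.ground_truth.trajectories["class"]) <= {"DR", "PAPA"}
        assert set(ds.trajectories["class"]) <= {"DR", "PAPA"}

    def test_bad_nonspecific_rate_rejected(self, acq):
        ds, schedule = self.make_dataset(acq, n_cells=3, n_traj=20, seed=5)
        with pytest.raises(ValueError, match="nonspecific_rate"):
            assign_papa_classes(ds, schedule, enrichment=2.0, nonspecific_rate=1.5, seed=0)


class TestRendering:
    def small_dataset(self, acq, traj_rows, cells=None):
        import smtpop.synthdata as sd

        cells = cells if cells is not None else pd.DataFrame(
            {"cell_id": [0], "fov_id": [0], "marker_intensity": [500.0],
             "nucleus_x": [5.0], "nucleus_y": [5.0], "nucleus_radius": [3.0]}
        )
        traj = pd.DataFrame(traj_rows, columns=["fov_id", "cell_id", "trajectory_id", "frame", "x_um", "y_um", "class"])
        return sd.SyntheticDataset(
            trajectories=traj, cells=cells,
            ground_truth=sd.GroundTruth(cells=pd.DataFrame(), trajectories=pd.DataFrame()),
            acq=acq, fov_size=10.0,
        )

    def test_single_spot_at_pixel_center_is_argmax(self, acq):
        # pixel (27, 31) center in um coordinates
        x = (31 + 0.0) * acq.pixel_size
        y = (27 + 0.0) * acq.pixel_size
        ds = self.small_dataset(acq, [[0, 0, 0, 0, x, y, "DR"]])
        movie, _, _ = render_frames(ds, acq, poisson_noise=False, background=0.0)
        assert np.unravel_index(movie[0].argmax(), movie[0].shape) == (27, 31)

    def test_empty_dataset_constant_background(self, acq):
        ds = self.small_dataset(acq, [])
        movie, bulk, _ = render_frames(ds, acq, poisson_noise=False, background=7.0, frames=[0])
        assert np.all(movie == 7.0)

    def test_two_spots_two_maxima(self, acq):
        x1, y1 = 20 * acq.pixel_size, 20 * acq.pixel_size
        x2 = 30 * acq.pixel_size  # 10 px apart
        ds = self.small_dataset(acq, [[0, 0, 0, 0, x1, y1, "DR"], [0, 0, 1, 0, x2, y1, "DR"]])
        movie, _, _ = render_frames(ds, acq, poisson_noise=False, background=0.0)
        from skimage.feature import peak_local_max

        peaks = peak_local_max(movie[0], min_distance=3, threshold_abs=movie[0].max() * 0.1)
        assert len(peaks) == 2

    def test_out_of_field_localizations_counted(self, acq):
        ds = self.small_dataset(acq, [[0, 0, 0, 0, 500.0, 500.0, "DR"]])
        _, _, meta = render_frames(ds, acq, poisson_noise=False)
        assert meta["n_clipped"] == 1
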