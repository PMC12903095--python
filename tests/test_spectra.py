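"""Spectrum-inference checks: likelihood, defocalization, EM recovery, FB."""

import numpy as np
import pytest
from scipy import integrate, stats

from smtpop import (
    AcquisitionParams,
    DiffusionGrid,
    DiffusionSpectrum,
    InferenceOptions,
    JumpSet,
    compute_fraction_bound,
    defocalization_weights,
    extract_jumps,
    infer_spectrum,
    jump_likelihood,
)
from smtpop.spectra import calibrate_sigma, slab_survival
import pandas as pd


def make_traj(frames, cell_id=0, tid=0):
    n = len(frames)
    return pd.DataFrame(
        {"cell_id": cell_id, "trajectory_id": tid, "frame": frames,
         "x_um": np.arange(n, dtype=float), "y_um": 0.0}
    )


def sample_r2(rng, D, n, acq):
    mean = 4.0 * (D * acq.dt + acq.sigma_loc**2)
    return rng.exponential(mean, size=n)


class TestExtractJumps:
    def test_no_gaps_gives_len_minus_one(self, acq):
        jumps = extract_jumps(make_traj([0, 1, 2, 3, 4]), acq)
        assert jumps[0].n_jumps == 4

    def test_gap_excludes_spanning_pair(self, acq):
        jumps = extract_jumps(make_traj([0, 1, 3, 4]), acq)
        assert jumps[0].n_jumps == 2

    def test_stationary_zero_error_zero_displacements(self, acq):
        df = make_traj([0, 1, 2])
        df["x_um"] = 1.0
        jumps = extract_jumps(df, acq)
        assert np.allclose(jumps[0].r2, 0.0)

    def test_zero_jump_cell_excluded(self, acq):
        df = pd.concat([make_traj([0, 5], cell_id=1), make_traj([0, 1], cell_id=2)])
        jumps = extract_jumps(df, acq)
        assert set(jumps) == {2}


class TestJumpLikelihood:
    def test_immobile_mean_is_4_sigma_sq(self):
        acq = AcquisitionParams(sigma_loc=0.035)
        mean = 4 * acq.sigma_loc**2
        assert np.isclose(mean, 0.0049)
        # density of Exp(mean) at 0 is 1/mean
        assert np.isclose(jump_likelihood(0.0, 0.0, acq), 1 / mean)

    def test_density_integrates_to_one(self, acq):
        for D in (0.0, 0.5, 20.0):
            val, _ = integrate.quad(lambda r2: jump_likelihood(r2, D, acq), 0, np.inf)
            assert abs(val - 1.0) < 1e-6

    def test_single_jump_mle(self, acq):
        # argmax over D of the density at one jump: D_hat = r2/(4 dt) - sigma^2/dt
        for r2 in (0.0001, 0.01, 0.3):
            d_hat = max(r2 / (4 * acq.dt) - acq.sigma_loc**2 / acq.dt, 0.0)
            fine = np.linspace(0, max(4 * d_hat, 1.0), 200_001)
            vals = jump_likelihood(r2, fine, acq)
            assert abs(fine[np.argmax(vals)] - d_hat) < fine[1] * 2

    def test_negative_r2_rejected(self, acq):
        with pytest.raises(ValueError):
            jump_likelihood(-1.0, 1.0, acq)


class TestDefocalization:
    def test_immobile_weight_is_one(self, acq):
        for mode in ("jump_count", "single_frame"):
            w = defocalization_weights(np.array([0.0, 1.0]), acq, mode=mode)
            assert np.isclose(w[0], 1.0, atol=1e-9)

    def test_monotone_nonincreasing(self, grid, acq):
        for mode in ("jump_count", "single_frame"):
            w = defocalization_weights(grid, acq, mode=mode)
            assert np.all(np.diff(w) <= 1e-12)

    def test_single_frame_matches_monte_carlo(self, acq):
        # 1e5 walkers; absorbing slab boundaries with Brownian-bridge
        # crossing probabilities so discrete substeps miss no excursions
        D, n, sub = 10.0, 100_000, 64
        rng = np.random.default_rng(0)
        dt_s = acq.dt / sub
        z = rng.uniform(0, acq.dz, size=n)
        alive = np.ones(n, dtype=bool)
        sd = np.sqrt(2 * D * dt_s)
        for _ in range(sub):
            z0 = z[alive]
            z1 = z0 + sd * rng.standard_normal(z0.size)
            inside = (z1 > 0) & (z1 < acq.dz)
            p_cross = np.ones(z0.size)
            p_cross[inside] = 1.0 - (
                (1 - np.exp(-z0[inside] * z1[inside] / (D * dt_s)))
                * (1 - np.exp(-(acq.dz - z0[inside]) * (acq.dz - z1[inside]) / (D * dt_s)))
            )
            survive = inside & (rng.random(z0.size) >= p_cross)
            idx = np.flatnonzero(alive)
            z[idx] = z1
            alive[idx[~survive]] = False
        mc = alive.mean()
        series = slab_survival(np.array([D]), acq.dt, acq.dz)[0]
        assert abs(series - mc) < 0.01


class TestInferSpectrum:
    def test_single_state_mode_recovered(self, grid, acq):
        rng = np.random.default_rng(1)
        js = JumpSet(0, sample_r2(rng, 1.0, 5000, acq), acq.dt)
        spec = infer_spectrum(js, grid, acq, InferenceOptions(correction=False))
        mode = grid.values[np.argmax(spec.occupations)]
        step = np.log10(grid.values[1] / grid.values[0])
        assert abs(np.log10(mode) - np.log10(1.0)) <= step * 1.5

    def test_all_zero_displacements_mass_at_lowest_point(self, grid):
        acq0 = AcquisitionParams(sigma_loc=1e-9)
        js = JumpSet(0, np.zeros(500), acq0.dt)
        spec = infer_spectrum(js, grid, acq0, InferenceOptions(correction=False))
        assert spec.occupations[0] > 0.999

    @pytest.mark.parametrize("alpha", [0.0, 1.0], ids=["plain_em", "dirichlet"])
    def test_5050_mixture_fraction_bound(self, grid, acq, alpha):
        opts = InferenceOptions(correction=False, dirichlet_alpha=alpha)
        for seed in range(5):
            rng = np.random.default_rng(seed)
            r2 = np.concatenate(
                [sample_r2(rng, 0.01, 2500, acq), sample_r2(rng, 5.0, 2500, acq)]
            )
            spec = infer_spectrum(JumpSet(0, r2, acq.dt), grid, acq, opts)
            assert 0.40 <= spec.fraction_bound <= 0.60

    def test_below_min_jumps_rejected(self, grid, acq):
        js = JumpSet(0, np.full(50, 0.01), acq.dt)
        with pytest.raises(ValueError, match="min_jumps"):
            infer_spectrum(js, grid, acq)

    def test_normalization_within_1e9(self, grid, acq):
        rng = np.random.default_rng(2)
        js = JumpSet(0, sample_r2(rng, 0.3, 1500, acq), acq.dt)
        spec = infer_spectrum(js, grid, acq)
        assert abs(spec.occupations.sum() - 1.0) < 1e-9
        assert 0.0 <= spec.fraction_bound <= 1.0

    def test_em_loglik_nondecreasing(self, grid, acq):
        rng = np.random.default_rng(3)
        r2 = np.concatenate([sample_r2(rng, 0.01, 400, acq), sample_r2(rng, 5.0, 400, acq)])
        trace: list = []
        infer_spectrum(JumpSet(0, r2, acq.dt), grid, acq, loglik_trace=trace)
        assert len(trace) > 2
        assert np.all(np.diff(trace) >= -1e-8)

    def test_deterministic(self, grid, acq):
        rng = np.random.default_rng(4)
        r2 = sample_r2(rng, 0.5, 800, acq)
        s1 = infer_spectrum(JumpSet(0, r2, acq.dt), grid, acq)
        s2 = infer_spectrum(JumpSet(0, r2.copy(), acq.dt), grid, acq)
        assert np.array_equal(s1.occupations, s2.occupations)


class TestFractionBound:
    def spectrum_with_mass(self, grid, where: dict):
        occ = np.zeros(len(grid))
        for d, m in where.items():
            occ[np.argmin(np.abs(grid.values - d))] = m
        occ /= occ.sum()
        return DiffusionSpectrum(grid=grid, occupations=occ, n_jumps=100)

    def test_all_bound(self, grid):
        assert compute_fraction_bound(self.spectrum_with_mass(grid, {0.01: 1.0})) == 1.0

    def test_all_free(self, grid):
        assert compute_fraction_bound(self.spectrum_with_mass(grid, {10.0: 1.0})) == 0.0

    def test_partial_mass(self, grid):
        spec = self.spectrum_with_mass(grid, {0.1: 0.4, 1.0: 0.6})
        assert np.isclose(compute_fraction_bound(spec, 0.15), 0.4)

    def test_threshold_outside_grid_rejected(self, grid):
        spec = self.spectrum_with_mass(grid, {0.1: 1.0})
        with pytest.raises(ValueError, match="outside"):
            compute_fraction_bound(spec, 1000.0)

    def test_monotone_in_threshold(self, grid, acq):
        rng = np.random.default_rng(5)
        r2 = np.concatenate([sample_r2(rng, 0.05, 300, acq), sample_r2(rng, 2.0, 300, acq)])
        spec = infer_spectrum(JumpSet(0, r2, acq.dt), grid, acq)
        thresholds = np.logspace(-1.8, 1.8, 30)
        values = [compute_fraction_bound(spec, t) for t in thresholds]
        assert np.all(np.diff(values) >= 0)


def test_uncorrected_fb_overestimates(grid, acq, single_state_spec):
    """Axial losses deplete fast molecules, so the uncorrected spectrum must
    overstate the bound fraction relative to the corrected one."""
    from smtpop import CellSpec, simulate_cell_trajectories, two_state_mixture

    spec = CellSpec(cell_id=0, states=two_state_mixture(0.4), n_trajectories=3000)
    traj, _ = simulate_cell_trajectories(spec, acq, seed=8)
    js = extract_jumps(traj, acq)[0]
    fb_corr = infer_spectrum(js, grid, acq, InferenceOptions(correction=True)).fraction_bound
    fb_raw = infer_spectrum(js, grid, acq, InferenceOptions(correction=False)).fraction_bound
    assert fb_raw > fb_corr
    assert abs(fb_corr - 0.4) < 0.1


def test_sigma_calibration_recovers_truth(acq):
    rng = np.random.default_rng(6)
    r2 = sample_r2(rng, 0.0, 50_000, acq)
    est = calibrate_sigma(JumpSet(0, r2, acq.dt), acq, D=0.0)
    assert abs(est - acq.sigma_loc) < 0.001
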