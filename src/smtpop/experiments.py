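"""Canned validation experiments over the synthetic study conditions.

Each function simulates a ground-truth-labeled dataset under the simulated
study's acquisition conditions (frame interval 0.01 s, localization error 0.035 um,
detection depth 0.7 um, mean track length 4, two diffusive states at 0.01 and
5 um^2/s), runs the pipeline, and measures how well the known truth is
recovered.  These experiments back the analysis drivers, the test suite and
the acceptance script; they are deterministic given their seeds.
"""

from __future__ import annotations

import logging


import numpy as np
import pandas as pd
from scipy import stats

from . import popstats, synthdata
from .acquisition import AcquisitionParams
from .papa import IlluminationSchedule, papa_compare, split_by_schedule
from .spectra import DiffusionGrid, InferenceOptions, extract_jumps, infer_spectra

logger = logging.getLogger(__name__)

DEFAULT_ACQ = AcquisitionParams()  # dt=0.01 s, sigma=0.035 um, dz=0.7 um, mean length 4

# reference per-experiment cell counts for the pooling bookkeeping check
POOLED_COUNTS = {
    "budding": [10, 44, 42, 56],
    "spheroid": [77, 73, 13, 24, 30, 58, 81, 71, 26, 32],
    "dhmg": [43, 23, 1, 34, 34],
    "h2b": [65, 30, 12, 50, 123, 81, 6],
}


def _spectra_for_population(
    config: synthdata.PopulationConfig,
    seed: int,
    acq: AcquisitionParams = DEFAULT_ACQ,
    grid: DiffusionGrid | None = None,
    options: InferenceOptions | None = None,
):
    grid = grid or DiffusionGrid.default()
    dataset = synthdata.simulate_population(config, acq, seed)
    jumps = extract_jumps(dataset.trajectories, acq)
    spectra, excluded = infer_spectra(jumps, grid, acq, options)
    return dataset, spectra, excluded, grid


def fb_recovery(
    fb_values=(0.2, 0.4, 0.6, 0.8),
    n_cells: int = 150,
    n_trajectories: int = 300,
    seed: int = 0,
    B: int = 1000,
    acq: AcquisitionParams = DEFAULT_ACQ,
) -> pd.DataFrame:
    """Two-state bound-fraction recovery across configured true FBs.

    Returns one row per setting with the true FB, the bootstrapped mean
    estimate with its 95% CI, the per-cell spread, and spectrum-normalization
    diagnostics (max |sum - 1| and a threshold-monotonicity flag across a
    sweep of thresholds).
    """
    rng = np.random.default_rng(seed)
    rows = []
    for fb in fb_values:
        config = synthdata.PopulationConfig(
            n_cells=n_cells, n_trajectories=n_trajectories, fb_mean=fb
        )
        _, spectra, excluded, grid = _spectra_for_population(config, int(rng.integers(2**31)), acq)
        exp = popstats.ExperimentSet.from_spectra(spectra, condition=f"fb{fb}")
        summary = popstats.bootstrap_summary(exp, B=B, seed=int(rng.integers(2**31)))
        occ = exp.spectra
        norm_err = float(np.abs(occ.sum(axis=1) - 1.0).max())
        thresholds = np.logspace(np.log10(0.02), np.log10(50), 25)
        masses = np.vstack([occ[:, grid.values < t].sum(axis=1) for t in thresholds])
        monotone = bool(np.all(np.diff(masses, axis=0) >= -1e-12))
        rows.append(
            {
                "true_fb": fb,
                "est_fb": summary.mean_fb,
                "ci_low": summary.ci_low,
                "ci_high": summary.ci_high,
                "cell_sd": float(exp.cells["fraction_bound"].std()),
                "n_cells": exp.n_cells,
                "n_excluded": len(excluded),
                "norm_err": norm_err,
                "fb_monotone_in_threshold": monotone,
            }
        )
    return pd.DataFrame(rows)


def control_separation(
    seed: int = 0,
    n_cells: int = 60,
    fb_immobile: float = 0.85,
    fb_free: float = 0.15,
    acq: AcquisitionParams = DEFAULT_ACQ,
) -> dict:
    """Separation between an immobile (H2B-like) and a freely diffusing
    (NLS-like) control population."""
    rng = np.random.default_rng(seed)
    results = {}
    fbs = {}
    for name, fb in (("h2b", fb_immobile), ("nls", fb_free)):
        config = synthdata.PopulationConfig(n_cells=n_cells, fb_mean=fb)
        _, spectra, _, _ = _spectra_for_population(config, int(rng.integers(2**31)), acq)
        exp = popstats.ExperimentSet.from_spectra(spectra, condition=name)
        summary = popstats.bootstrap_summary(exp, seed=int(rng.integers(2**31)))
        results[f"fb_{name}"] = summary.mean_fb
        fbs[name] = exp.cells["fraction_bound"].values
    comparison = popstats.compare_fb(fbs["h2b"], fbs["nls"], method="mann_whitney")
    results["fb_difference"] = results["fb_h2b"] - results["fb_nls"]
    results["p"] = comparison["p"]
    results["n_per_group"] = n_cells
    return results


def bootstrap_coverage(
    n_repeats: int = 100,
    n_cells: int = 50,
    n_trajectories: int = 300,
    B: int = 500,
    true_fb: float = 0.40,
    seed: int = 0,
    acq: AcquisitionParams = DEFAULT_ACQ,
) -> dict:
    """Fraction of seeded repeats whose 95% bootstrap CI contains the truth."""
    rng = np.random.default_rng(seed)
    covered = 0
    widths = []
    for _ in range(n_repeats):
        config = synthdata.PopulationConfig(
            n_cells=n_cells, n_trajectories=n_trajectories, fb_mean=true_fb
        )
        _, spectra, _, _ = _spectra_for_population(config, int(rng.integers(2**31)), acq)
        exp = popstats.ExperimentSet.from_spectra(spectra)
        summary = popstats.bootstrap_summary(exp, B=B, seed=int(rng.integers(2**31)))
        if summary.ci_low <= true_fb <= summary.ci_high:
            covered += 1
        widths.append(summary.ci_high - summary.ci_low)
    return {
        "covered": covered,
        "n_repeats": n_repeats,
        "coverage": covered / n_repeats,
        "mean_ci_width": float(np.mean(widths)),
    }


def marker_stratified_recovery(
    n_seeds: int = 20,
    n_cells: int = 120,
    fb_positive: float = 0.48,
    fb_negative: float = 0.38,
    seed: int = 0,
    acq: AcquisitionParams = DEFAULT_ACQ,
) -> dict:
    """Marker-stratified class-mean recovery and difference-sign stability.

    Positive (stem-like) cells carry the higher configured bound fraction;
    the per-FOV Otsu classifier assigns classes from the simulated bimodal
    marker intensities, and class means are estimated from the stratified
    spectra.
    """
    rng = np.random.default_rng(seed)
    pos_means, neg_means, signs = [], [], []
    for _ in range(n_seeds):
        config = synthdata.PopulationConfig(
            n_cells=n_cells,
            class_fb={"positive": fb_positive, "negative": fb_negative},
            use_marker=True,
        )
        dataset, spectra, _, _ = _spectra_for_population(config, int(rng.integers(2**31)), acq)
        from .imaging import classify_marker

        records = classify_marker(dataset.cells, method="otsu_per_fov")
        exp = popstats.ExperimentSet.from_spectra(
            spectra, cell_table=records[["cell_id", "marker_class"]]
        )
        fb = exp.cells.set_index("cell_id")["fraction_bound"]
        classes = exp.cells.set_index("cell_id")["marker_class"]
        pos = fb[classes == "positive"]
        neg = fb[classes == "negative"]
        pos_means.append(float(pos.mean()))
        neg_means.append(float(neg.mean()))
        signs.append(float(pos.mean() - neg.mean()) > 0)
    return {
        "fb_positive_true": fb_positive,
        "fb_negative_true": fb_negative,
        "fb_positive_est": float(np.mean(pos_means)),
        "fb_negative_est": float(np.mean(neg_means)),
        "sign_correct_rate": float(np.mean(signs)),
        "n_seeds": n_seeds,
        "per_seed_positive": pos_means,
        "per_seed_negative": neg_means,
    }


def null_calibration(
    n_repeats: int = 200,
    n_cells: int = 50,
    alpha: float = 0.05,
    seed: int = 0,
    method: str = "mann_whitney",
) -> dict:
    """Type-I calibration of the group comparison and the FB-feature
    correlation on independent null draws at the per-cell statistic level.

    Per-cell FBs are drawn from one truncated-normal distribution for both
    groups (no group effect) and features independently of FB (no
    correlation); rejection rates and the KS uniformity of correlation
    p-values are reported.
    """
    rng = np.random.default_rng(seed)
    rejections = 0
    corr_pvalues = []
    for _ in range(n_repeats):
        a = np.clip(rng.normal(0.4, 0.1, n_cells), 0, 1)
        b = np.clip(rng.normal(0.4, 0.1, n_cells), 0, 1)
        res = popstats.compare_fb(a, b, method=method, seed=int(rng.integers(2**31)))
        if res["p"] <= alpha:
            rejections += 1
        cells = pd.DataFrame(
            {
                "cell_id": np.arange(n_cells),
                "fraction_bound": np.clip(rng.normal(0.4, 0.1, n_cells), 0, 1),
                "nuclear_area": rng.normal(60, 15, n_cells),
            }
        )
        grid = DiffusionGrid.default()
        exp = popstats.ExperimentSet(
            experiment_id=0,
            cells=cells,
            spectra=np.full((n_cells, len(grid)), 1.0 / len(grid)),
            grid=grid,
        )
        corr = popstats.correlate_fb_feature(exp, "nuclear_area")
        corr_pvalues.append(corr.p)
    ks = stats.kstest(corr_pvalues, "uniform")
    return {
        "rejection_rate": rejections / n_repeats,
        "n_repeats": n_repeats,
        "alpha": alpha,
        "corr_ks_p": float(ks.pvalue),
    }


def papa_power(
    n_seeds: int = 10,
    n_cells: int = 120,
    fb_dr: float = 0.41,
    fb_papa: float = 0.52,
    n_trajectories: int = 300,
    seed: int = 0,
    acq: AcquisitionParams = DEFAULT_ACQ,
    p_threshold: float = 1e-4,
) -> dict:
    """Detection of a PAPA-vs-DR bound-fraction excess at the design effect.

    Each seed simulates an oligomer/monomer population whose DR and PAPA
    trajectory classes have the configured bound fractions, splits
    trajectories by the illumination schedule, and tests delta = FB_PAPA -
    FB_DR with the paired permutation test.
    """
    rng = np.random.default_rng(seed)
    design = synthdata.PapaDesign.from_class_fb(fb_dr=fb_dr, fb_papa=fb_papa)
    schedule = IlluminationSchedule.alternating(n_cycles=400)
    options = InferenceOptions(min_jumps=50)
    successes, deltas, pvalues = [], [], []
    for _ in range(n_seeds):
        config = synthdata.PopulationConfig(n_cells=n_cells, n_trajectories=n_trajectories)
        dataset = synthdata.simulate_papa_population(
            config, design, schedule, acq, int(rng.integers(2**31))
        )
        dr, papa, _ = split_by_schedule(dataset.trajectories, schedule)
        comparison = papa_compare(
            dr, papa, acq, options=options, seed=int(rng.integers(2**31))
        )
        deltas.append(comparison.delta)
        pvalues.append(comparison.p)
        successes.append(comparison.delta > 0 and comparison.p <= p_threshold)
    return {
        "success_rate": float(np.mean(successes)),
        "n_seeds": n_seeds,
        "mean_delta": float(np.mean(deltas)),
        "mean_fb_dr": fb_dr,
        "mean_fb_papa": fb_papa,
        "pvalues": pvalues,
    }


def papa_null_calibration(
    n_repeats: int = 200,
    n_cells: int = 12,
    n_trajectories: int = 200,
    alpha: float = 0.05,
    seed: int = 0,
    acq: AcquisitionParams = DEFAULT_ACQ,
) -> dict:
    """Type-I rate of the paired PAPA comparison under enrichment = 1."""
    rng = np.random.default_rng(seed)
    design = synthdata.PapaDesign(enrichment=1.0)
    schedule = IlluminationSchedule.alternating(n_cycles=200)
    # coarse bins: at ~150 jumps/cell the bin resolution is still far below
    # the grid spacing, and the null only needs the test's type-I behavior
    options = InferenceOptions(min_jumps=30, n_bins=64)
    rejections = 0
    for _ in range(n_repeats):
        config = synthdata.PopulationConfig(n_cells=n_cells, n_trajectories=n_trajectories)
        dataset = synthdata.simulate_papa_population(
            config, design, schedule, acq, int(rng.integers(2**31))
        )
        dr, papa, _ = split_by_schedule(dataset.trajectories, schedule)
        comparison = papa_compare(
            dr, papa, acq, options=options, seed=int(rng.integers(2**31)),
            n_permutations=2000, B=200,
        )
        if comparison.p <= alpha:
            rejections += 1
    return {"rejection_rate": rejections / n_repeats, "n_repeats": n_repeats, "alpha": alpha}


def geometry_oracle(n_layouts: int = 50, n_nuclei: int = 12, seed: int = 0) -> dict:
    """Two-nearest-nuclei distances vs a brute-force all-pairs oracle, and
    rendered-disk segmentation areas vs pi r^2."""
    from .imaging import SegmentationParams, nucleus_features, segment_nuclei, two_nearest_distances

    rng = np.random.default_rng(seed)
    max_err = 0.0
    for _ in range(n_layouts):
        pts = rng.uniform(0, 100, size=(n_nuclei, 2))
        package = two_nearest_distances(pts)
        # independent oracle: explicit all-pairs loops with running minima
        brute = np.empty(n_nuclei)
        for i in range(n_nuclei):
            best, second = np.inf, np.inf
            for j in range(n_nuclei):
                if i == j:
                    continue
                dist = ((pts[i, 0] - pts[j, 0]) ** 2 + (pts[i, 1] - pts[j, 1]) ** 2) ** 0.5
                if dist < best:
                    best, second = dist, best
                elif dist < second:
                    second = dist
            brute[i] = (best + second) / 2.0
        max_err = max(max_err, float(np.abs(brute - package).max()))

    # rendered disks -> segmentation -> area oracle
    px = 0.2
    radii_um = [3.0, 4.0, 5.0, 3.5, 4.5]
    centers = [(15, 15), (15, 45), (45, 15), (45, 45), (30, 30)]
    size = int(60 / px)
    yy, xx = np.mgrid[0:size, 0:size]
    img = np.zeros((size, size))
    for (cy, cx), r in zip(centers, radii_um):
        img[((xx * px - cx) ** 2 + (yy * px - cy) ** 2) <= r**2] = 1000.0
    mask = segment_nuclei(img, SegmentationParams(min_area_px=100, watershed_footprint_px=10))
    feats = nucleus_features(mask, px)
    areas = np.sort(feats["nuclear_area"].values)
    expected = np.sort([np.pi * r**2 for r in radii_um])
    area_rel_err = float(np.abs(areas - expected).max() / expected.max()) if len(areas) == 5 else np.inf
    rel = np.abs(areas - expected) / expected if len(areas) == 5 else np.array([np.inf])
    return {
        "n_layouts": n_layouts,
        "max_distance_error": max_err,
        "n_disks_found": int(len(areas)),
        "max_area_rel_err": float(rel.max()),
    }


def tracking_identity(seed: int = 0, n_molecules: int = 6, n_frames: int = 25) -> dict:
    """End-to-end detection+linking vs ground truth on a noiseless movie.

    Well-separated slow molecules are rendered without noise; the recovered
    trajectory set must partition the detected localizations exactly as the
    ground truth partitions the true ones.
    """
    from .imaging import DetectionParams, default_max_radius, detect_movie, link_localizations

    acq = AcquisitionParams(sigma_loc=1e-6, pixel_size=0.1)
    rng = np.random.default_rng(seed)
    # molecules on a coarse lattice so nearest-neighbor linking is unambiguous
    centers = [(10 + 12 * (i % 3), 10 + 12 * (i // 3)) for i in range(n_molecules)]
    specs = [
        synthdata.CellSpec(
            cell_id=i,
            states=[synthdata.MotionState("slow", 0.05, 1.0)],
            n_trajectories=1,
            nucleus_center=c,
            nucleus_radius=3.0,
            fov_id=0,
        )
        for i, c in enumerate(centers)
    ]
    frames, truths = [], []
    for spec in specs:
        t, gt = synthdata.simulate_cell_trajectories(
            spec, acq, int(rng.integers(2**31)),
            bleaching=False, axial_truncation=False, fixed_length=n_frames, movie_length=1,
        )
        t["frame"] = np.arange(len(t))
        frames.append(t)
        truths.append(gt)
    traj = pd.concat(frames, ignore_index=True)
    dataset = synthdata.SyntheticDataset(
        trajectories=traj,
        cells=pd.DataFrame(
            {
                "cell_id": [s.cell_id for s in specs],
                "fov_id": 0,
                "marker_intensity": 100.0,
                "nucleus_x": [c[0] for c in centers],
                "nucleus_y": [c[1] for c in centers],
                "nucleus_radius": 3.0,
            }
        ),
        ground_truth=synthdata.GroundTruth(cells=pd.DataFrame(), trajectories=pd.concat(truths)),
        acq=acq,
        fov_size=46.0,
    )
    movie, _, meta = synthdata.render_frames(
        dataset, acq, poisson_noise=False, background=0.0, photons=2000.0, seed=0
    )
    locs = detect_movie(movie, DetectionParams(threshold=0.05), pixel_size=acq.pixel_size)
    linked = link_localizations(locs, max_radius=default_max_radius(0.05, acq.dt))
    # match detections to true localizations by position, then compare partitions
    true_partition: dict = {}
    matched_partition: dict = {}
    identical = True
    for f in range(n_frames):
        det = linked[linked["frame"] == f]
        tru = traj[traj["frame"] == f]
        if len(det) != len(tru):
            identical = False
            break
        d = np.sqrt(
            (det["x_um"].values[:, None] - tru["x_um"].values[None, :]) ** 2
            + (det["y_um"].values[:, None] - tru["y_um"].values[None, :]) ** 2
        )
        assign = d.argmin(axis=1)
        if len(set(assign)) != len(assign) or d[np.arange(len(assign)), assign].max() > 0.05:
            identical = False
            break
        for det_row, true_idx in zip(det.itertuples(), assign):
            true_row = tru.iloc[true_idx]
            true_partition.setdefault((true_row["cell_id"]), set()).add((f, true_idx))
            matched_partition.setdefault(det_row.trajectory_id, set()).add((f, true_idx))
    if identical:
        identical = set(map(frozenset, true_partition.values())) == set(
            map(frozenset, matched_partition.values())
        )
    return {
        "identical": bool(identical),
        "n_true_trajectories": n_molecules,
        "n_recovered_trajectories": int(linked["trajectory_id"].nunique()),
        "n_localizations": int(len(linked)),
    }


def pooled_counts() -> dict:
    """Pooled cell counts of multi-experiment reference campaigns, reproduced
    by the pooling operation on per-experiment cell tables."""
    grid = DiffusionGrid.default()
    out = {}
    for condition, counts in POOLED_COUNTS.items():
        sets = []
        for e_i, n in enumerate(counts):
            cells = pd.DataFrame(
                {"cell_id": np.arange(n), "fraction_bound": np.full(n, 0.5)}
            )
            sets.append(
                popstats.ExperimentSet(
                    experiment_id=e_i,
                    cells=cells,
                    spectra=np.full((n, len(grid)), 1.0 / len(grid)),
                    grid=grid,
                    condition=condition,
                )
            )
        pooled = popstats.combine_experiments(sets, condition=condition)
        out[condition] = pooled.n_cells
    return out
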