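"""Configuration, file formats and end-to-end orchestration.

Formats: trajectory tables are comma-separated UTF-8 CSV with a mandatory
header (``fov_id, cell_id, trajectory_id, frame, x_um, y_um, class``); images
and label masks are single-plane 16-bit TIFF; configs are YAML with a strict
schema (unknown keys rejected); reports are JSON plus CSV tables.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .acquisition import AcquisitionParams
from .spectra import (
    DEFAULT_FB_THRESHOLD,
    DiffusionGrid,
    InferenceOptions,
    extract_jumps,
    infer_spectra,
)
from . import popstats, synthdata

logger = logging.getLogger(__name__)

SCHEMA_VERSION = "1"
TRAJECTORY_COLUMNS = synthdata.TRAJECTORY_COLUMNS


@dataclass
class PipelineConfig:
    """Validated end-to-end configuration."""

    acquisition: AcquisitionParams = field(default_factory=AcquisitionParams)
    grid_d_min: float = 0.01
    grid_d_max: float = 100.0
    grid_points: int = 101
    fb_threshold: float = DEFAULT_FB_THRESHOLD
    min_jumps: int = 100
    bootstrap_B: int = 1000
    seed: int = 0
    classifier: str = "otsu_per_fov"
    test: str = "mann_whitney"
    correction: bool = True
    simulation: dict | None = None    # PopulationConfig fields; None = read inputs
    trajectories_path: str | None = None
    condition: str = "condition"

    _KNOWN = {
        "acquisition", "grid_d_min", "grid_d_max", "grid_points", "fb_threshold",
        "min_jumps", "bootstrap_B", "seed", "classifier", "test", "correction",
        "simulation", "trajectories_path", "condition",
    }

    def __post_init__(self) -> None:
        if not self.grid_d_min < self.fb_threshold < self.grid_d_max:
            raise ValueError("fb_threshold must lie inside the grid span")
        if self.min_jumps < 1:
            raise ValueError("min_jumps must be >= 1")
        if self.bootstrap_B < 100:
            raise ValueError("bootstrap_B must be >= 100")
        if self.classifier not in {"otsu_per_fov", "fixed_threshold"}:
            raise ValueError(f"unknown classifier {self.classifier!r}")
        if self.test not in {"mann_whitney", "permutation"}:
            raise ValueError(f"unknown test {self.test!r}")
        if self.simulation is None and self.trajectories_path is None:
            raise ValueError("config must request a simulation or name a trajectories_path")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ValueError("config root must be a mapping")
        unknown = set(raw) - cls._KNOWN
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "acquisition" in raw:
            raw["acquisition"] = AcquisitionParams(**raw["acquisition"])
        return cls(**raw)

    def grid(self) -> DiffusionGrid:
        return DiffusionGrid.default(self.grid_d_min, self.grid_d_max, self.grid_points)

    def inference_options(self) -> InferenceOptions:
        return InferenceOptions(
            correction=self.correction,
            min_jumps=self.min_jumps,
            fb_threshold=self.fb_threshold,
        )

    def digest(self) -> str:
        payload = {k: v for k, v in asdict(self).items()}
        return hashlib.sha256(json.dumps(payload, sort_keys=True, default=str).encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# Image I/O (single-plane 16-bit TIFF per channel)


def write_image(image: np.ndarray, path) -> None:
    """Write a grayscale image or label mask as a single-plane 16-bit TIFF."""
    import tifffile

    arr = np.asarray(image)
    if arr.ndim != 2:
        raise ValueError(f"expected a 2D image, got ndim={arr.ndim}")
    if arr.dtype.kind in "iu":
        if arr.max(initial=0) > np.iinfo(np.uint16).max or arr.min(initial=0) < 0:
            raise ValueError("integer image does not fit in uint16")
        out = arr.astype(np.uint16)
    else:
        out = np.clip(arr, 0, np.iinfo(np.uint16).max).round().astype(np.uint16)
    tifffile.imwrite(path, out)


def read_image(path) -> np.ndarray:
    """Read a single-plane TIFF written by :func:`write_image`."""
    import tifffile

    return tifffile.imread(path)


# ---------------------------------------------------------------------------
# Trajectory CSV I/O


def write_trajectories(trajectories: pd.DataFrame, path) -> None:
    missing = set(TRAJECTORY_COLUMNS) - set(trajectories.columns)
    if missing:
        raise ValueError(f"trajectory table is missing columns: {sorted(missing)}")
    trajectories[TRAJECTORY_COLUMNS].to_csv(path, index=False)


def read_trajectories(path) -> pd.DataFrame:
    """Read and validate a trajectory CSV.

    Rows with non-finite coordinates are rejected (logged); trajectories with
    non-strictly-increasing frames are dropped and counted.  An empty file
    with a header yields an empty table, not an error.
    """
    df = pd.read_csv(path)
    missing = set(TRAJECTORY_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"trajectory file {path} is missing columns: {sorted(missing)}")
    if df.empty:
        return df[TRAJECTORY_COLUMNS]
    for col in ("x_um", "y_um", "frame"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    bad = ~np.isfinite(df["x_um"]) | ~np.isfinite(df["y_um"]) | ~np.isfinite(df["frame"])
    if bad.any():
        logger.warning("%d malformed rows rejected from %s", int(bad.sum()), path)
        df = df[~bad]
    df["frame"] = df["frame"].astype(np.int64)
    key = ["fov_id", "cell_id", "trajectory_id"]
    n_dropped = 0
    keep_parts = []
    for _, sub in df.groupby(key, sort=False):
        frames = sub["frame"].values
        order = np.argsort(frames, kind="mergesort")
        if np.any(np.diff(frames[order]) <= 0):
            n_dropped += 1
            continue
        keep_parts.append(sub.iloc[order])
    if n_dropped:
        logger.warning("%d trajectories dropped with non-monotone frames", n_dropped)
    if not keep_parts:
        return df.iloc[0:0][TRAJECTORY_COLUMNS]
    return pd.concat(keep_parts, ignore_index=True)[TRAJECTORY_COLUMNS]


# ---------------------------------------------------------------------------
# Pipeline


@dataclass
class Report:
    """End-to-end result: summaries, per-cell table, provenance."""

    condition: str
    summary: popstats.BootstrapSummary
    cells: pd.DataFrame
    spectra: np.ndarray
    grid: DiffusionGrid
    correlations: dict
    comparisons: dict
    provenance: dict

    def to_payload(self) -> dict:
        """JSON-serializable payload (excluding bulky tables)."""
        return {
            "schema_version": SCHEMA_VERSION,
            "condition": self.condition,
            "summary": {
                "mean_fb": self.summary.mean_fb,
                "ci_low": self.summary.ci_low,
                "ci_high": self.summary.ci_high,
                "n_cells": self.summary.n_cells,
                "B": self.summary.B,
                "seed": self.summary.seed,
            },
            "correlations": {
                k: {kk: (None if isinstance(vv, float) and not np.isfinite(vv) else vv)
                    for kk, vv in v.items()}
                for k, v in self.correlations.items()
            },
            "comparisons": self.comparisons,
            "provenance": self.provenance,
        }


def run_pipeline(config: PipelineConfig) -> Report:
    """Run simulate|read -> jumps -> spectra -> population stats.

    Stages run in a fixed order; any stage failure aborts with the stage name
    in the exception message; identical config and seed give an identical
    report payload.
    """
    provenance: dict = {"config_digest": config.digest(), "seed": config.seed, "qc": {}}
    rng = np.random.default_rng(config.seed)
    acq = config.acquisition
    stage = "input"
    try:
        if config.simulation is not None:
            sim_kwargs = dict(config.simulation)
            marker_kwargs = sim_kwargs.pop("marker", None)
            if marker_kwargs:
                sim_kwargs["marker"] = synthdata.MarkerModel(**marker_kwargs)
            pop_config = synthdata.PopulationConfig(**sim_kwargs)
            dataset = synthdata.simulate_population(pop_config, acq, int(rng.integers(2**31)))
            trajectories = dataset.trajectories
            cell_table = dataset.cells
            provenance["qc"]["n_cells_simulated"] = len(dataset.cells)
        else:
            stage = "read"
            trajectories = read_trajectories(config.trajectories_path)
            cell_table = None
        provenance["qc"]["n_localizations"] = int(len(trajectories))

        stage = "spectra"
        jumps = extract_jumps(trajectories, acq)
        provenance["qc"]["n_cells_with_jumps"] = len(jumps)
        spectra, excluded = infer_spectra(jumps, config.grid(), acq, config.inference_options())
        provenance["qc"]["n_cells_excluded_min_jumps"] = len(excluded)
        provenance["qc"]["excluded_cells"] = [str(c) for c in excluded]
        if not spectra:
            raise ValueError("no cells passed the jump QC gate")

        stage = "popstats"
        experiment = popstats.ExperimentSet.from_spectra(
            spectra,
            experiment_id=0,
            condition=config.condition,
            cell_table=cell_table,
            fb_threshold=config.fb_threshold,
        )
        summary = popstats.bootstrap_summary(
            experiment, B=config.bootstrap_B, seed=int(rng.integers(2**31)),
            fb_threshold=config.fb_threshold,
        )
        correlations = {}
        for feature in ("nuclear_area", "two_nearest_dist", "tf_intensity"):
            if feature in experiment.cells.columns:
                try:
                    res = popstats.correlate_fb_feature(experiment, feature)
                except ValueError:
                    continue
                correlations[feature] = {
                    "R": res.R, "p": res.p, "slope": res.slope,
                    "intercept": res.intercept, "n": res.n, "defined": res.defined,
                }
        comparisons: dict = {}
        if "marker_class" in experiment.cells.columns:
            classes = experiment.cells["marker_class"]
            pos = experiment.cells.loc[classes == "positive", "fraction_bound"].values
            neg = experiment.cells.loc[classes == "negative", "fraction_bound"].values
            if len(pos) >= 3 and len(neg) >= 3:
                comparisons["positive_vs_negative"] = popstats.compare_fb(
                    pos, neg, method=config.test, seed=int(rng.integers(2**31))
                )
        return Report(
            condition=config.condition,
            summary=summary,
            cells=experiment.cells,
            spectra=experiment.spectra,
            grid=experiment.grid,
            correlations=correlations,
            comparisons=comparisons,
            provenance=provenance,
        )
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc


def write_report(report: Report, out_dir, plots: bool = False) -> dict:
    """Write the JSON summary, per-cell CSV and spectra table.

    Returns the paths written.  With ``plots=True`` a mean-spectrum figure
    and a single-cell heatmap (ordered by decreasing FB) are also written.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    payload = report.to_payload()
    paths["summary"] = out / "report.json"
    with open(paths["summary"], "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
    paths["cells"] = out / "cells.csv"
    report.cells.to_csv(paths["cells"], index=False)
    spectra_df = pd.DataFrame(report.spectra, columns=[f"{d:.6g}" for d in report.grid.values])
    spectra_df.insert(0, "cell_id", report.cells["cell_id"].values)
    paths["spectra"] = out / "spectra.csv"
    spectra_df.to_csv(paths["spectra"], index=False)
    if plots:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, axes = plt.subplots(1, 2, figsize=(10, 4))
        axes[0].semilogx(report.grid.values, report.summary.mean_spectrum)
        axes[0].axvline(DEFAULT_FB_THRESHOLD, ls="--", c="gray")
        axes[0].set_xlabel("D (um$^2$/s)")
        axes[0].set_ylabel("occupation")
        axes[0].set_title(f"{report.condition}: mean spectrum, FB={report.summary.mean_fb:.2f}")
        order = np.argsort(-report.cells["fraction_bound"].values)
        axes[1].imshow(report.spectra[order], aspect="auto", cmap="viridis")
        axes[1].set_xlabel("grid index")
        axes[1].set_ylabel("cells (FB decreasing)")
        fig.tight_layout()
        paths["figure"] = out / "spectra.png"
        fig.savefig(paths["figure"], dpi=120)
        plt.close(fig)
    return paths
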