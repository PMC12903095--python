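"""Population-level statistics over single-cell diffusion spectra.

The resampling unit throughout is the cell: experiments are pooled by cell,
mean spectra and fraction-bound statistics are bootstrapped by resampling
cells with replacement, group comparisons act on per-cell fraction-bound
values, and clustering/ordering operates on per-cell occupation vectors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy

from .spectra import DEFAULT_FB_THRESHOLD, DiffusionGrid, DiffusionSpectrum

logger = logging.getLogger(__name__)


@dataclass
class ExperimentSet:
    """Cells (with spectra) from one experiment or pooled experiments."""

    experiment_id: object
    cells: pd.DataFrame          # one row per cell; includes 'cell_id', 'fraction_bound'
    spectra: np.ndarray          # (n_cells, K) occupation vectors aligned with `cells`
    grid: DiffusionGrid
    condition: str = ""

    def __post_init__(self) -> None:
        if self.spectra.shape[0] != len(self.cells):
            raise ValueError("spectra rows must match the cell table")
        if self.spectra.shape[1] != len(self.grid):
            raise ValueError("spectra columns must match the grid")
        keys = self._keys()
        if keys.duplicated().any():
            raise ValueError("duplicate cell keys within the experiment set")

    def _keys(self) -> pd.Series:
        if "experiment_id" in self.cells.columns:
            return self.cells["experiment_id"].astype(str) + "/" + self.cells["cell_id"].astype(str)
        return self.cells["cell_id"].astype(str)

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    @classmethod
    def from_spectra(
        cls,
        spectra: list[DiffusionSpectrum],
        experiment_id: object = 0,
        condition: str = "",
        cell_table: pd.DataFrame | None = None,
        fb_threshold: float = DEFAULT_FB_THRESHOLD,
    ) -> "ExperimentSet":
        if not spectra:
            raise ValueError("need at least one spectrum")
        grid = spectra[0].grid
        mat = np.vstack([s.occupations for s in spectra])
        cells = pd.DataFrame(
            {
                "cell_id": [s.cell_id for s in spectra],
                "n_jumps": [s.n_jumps for s in spectra],
                "fraction_bound": [
                    float(s.occupations[grid.values < fb_threshold].sum()) for s in spectra
                ],
            }
        )
        if cell_table is not None:
            extra = cell_table.set_index("cell_id")
            for col in extra.columns:
                if col not in cells.columns:
                    cells[col] = cells["cell_id"].map(extra[col])
        return cls(experiment_id=experiment_id, cells=cells, spectra=mat, grid=grid, condition=condition)


@dataclass
class BootstrapSummary:
    """Cell-resampled mean spectrum and fraction bound with a percentile CI."""

    mean_spectrum: np.ndarray
    mean_fb: float
    ci_low: float
    ci_high: float
    n_cells: int
    B: int
    seed: int
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not (0 <= self.ci_low <= self.mean_fb + 1e-12 and self.mean_fb - 1e-12 <= self.ci_high <= 1):
            # the point estimate is the FB of the full-sample mean spectrum and can
            # in principle fall outside the replicate percentiles; flag, don't fail
            logger.warning(
                "bootstrap point estimate %.4f outside CI [%.4f, %.4f]",
                self.mean_fb, self.ci_low, self.ci_high,
            )


@dataclass
class CorrelationResult:
    """Pearson correlation of per-cell fraction bound with a feature."""

    R: float
    p: float
    slope: float
    intercept: float
    n: int
    defined: bool = True


def combine_experiments(experiments: list[ExperimentSet], condition: str = "") -> ExperimentSet:
    """Pool cells across experiments with (experiment_id, cell_id) keys.

    The pooled count equals the sum of per-experiment counts; duplicate keys
    are rejected.
    """
    if not experiments:
        raise ValueError("need at least one experiment")
    grid = experiments[0].grid
    for exp in experiments[1:]:
        if not np.allclose(exp.grid.values, grid.values):
            raise ValueError("experiments use incompatible diffusion grids")
    frames = []
    for exp in experiments:
        cells = exp.cells.copy()
        cells["experiment_id"] = exp.experiment_id
        frames.append(cells)
    pooled_cells = pd.concat(frames, ignore_index=True)
    keys = pooled_cells["experiment_id"].astype(str) + "/" + pooled_cells["cell_id"].astype(str)
    if keys.duplicated().any():
        dupes = keys[keys.duplicated()].unique()[:5]
        raise ValueError(f"duplicate (experiment_id, cell_id) keys: {list(dupes)}")
    pooled_spectra = np.vstack([exp.spectra for exp in experiments])
    pooled = ExperimentSet(
        experiment_id="pooled",
        cells=pooled_cells,
        spectra=pooled_spectra,
        grid=grid,
        condition=condition or experiments[0].condition,
    )
    pooled.cells.attrs["provenance"] = pd.DataFrame(
        {
            "experiment_id": [e.experiment_id for e in experiments],
            "n_cells": [e.n_cells for e in experiments],
        }
    )
    assert pooled.n_cells == sum(e.n_cells for e in experiments)
    return pooled


def bootstrap_summary(
    experiment: ExperimentSet,
    B: int = 1000,
    seed: int = 0,
    fb_threshold: float = DEFAULT_FB_THRESHOLD,
) -> BootstrapSummary:
    """Bootstrap the mean spectrum's fraction bound by resampling cells.

    The point estimate is the FB of the full-sample mean spectrum; the CI is
    the 2.5/97.5 percentile of replicate FBs.  A single-cell input yields a
    degenerate summary with the CI collapsed to the point estimate.
    """
    n = experiment.n_cells
    if n < 1:
        raise ValueError("bootstrap requires at least one cell")
    below = experiment.grid.values < fb_threshold
    mean_spectrum = experiment.spectra.mean(axis=0)
    mean_fb = float(mean_spectrum[below].sum())
    if n == 1:
        logger.warning("bootstrap over a single cell: degenerate CI")
        return BootstrapSummary(mean_spectrum, mean_fb, mean_fb, mean_fb, 1, B, seed, degenerate=True)
    if B < 100:
        raise ValueError(f"B must be >= 100, got {B}")
    rng = np.random.default_rng(seed)
    fb_per_cell = experiment.spectra[:, below].sum(axis=1)
    idx = rng.integers(0, n, size=(B, n))
    replicate_fb = fb_per_cell[idx].mean(axis=1)
    ci_low, ci_high = np.percentile(replicate_fb, [2.5, 97.5])
    return BootstrapSummary(mean_spectrum, mean_fb, float(ci_low), float(ci_high), n, B, seed)


def compare_fb(
    group_a: np.ndarray,
    group_b: np.ndarray,
    method: str = "mann_whitney",
    seed: int | None = None,
    n_permutations: int = 10_000,
) -> dict:
    """Two-sided comparison of per-cell fraction-bound distributions.

    ``mann_whitney`` uses the Mann-Whitney U test; ``permutation`` uses the
    difference of group means with label permutations.  Returns p, group
    means and sizes.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValueError("each group needs at least 3 cells")
    if method == "mann_whitney":
        stat, p = stats.mannwhitneyu(a, b, alternative="two-sided")
    elif method == "permutation":
        rng = np.random.default_rng(seed)
        observed = a.mean() - b.mean()
        pooled = np.concatenate([a, b])
        n_a = a.size
        count = 0
        for _ in range(n_permutations):
            rng.shuffle(pooled)
            if abs(pooled[:n_a].mean() - pooled[n_a:].mean()) >= abs(observed) - 1e-15:
                count += 1
        p = (count + 1) / (n_permutations + 1)
        stat = observed
    else:
        raise ValueError(f"unknown comparison method {method!r}")
    return {
        "p": float(p),
        "statistic": float(stat),
        "mean_a": float(a.mean()),
        "mean_b": float(b.mean()),
        "n_a": int(a.size),
        "n_b": int(b.size),
        "method": method,
    }


def cluster_and_order(
    experiment: ExperimentSet,
    mode: str = "fb_sort",
    n_clusters: int | None = None,
    fb_threshold: float = DEFAULT_FB_THRESHOLD,
) -> dict:
    """Order single-cell spectra for heatmap display.

    ``fb_sort`` orders by strictly decreasing fraction bound (ties broken by
    cell key); ``hierarchical`` runs Ward linkage on Euclidean distances
    between occupation vectors and returns the leaf order plus cluster labels
    at the requested cut.
    """
    below = experiment.grid.values < fb_threshold
    fb = experiment.spectra[:, below].sum(axis=1)
    if mode == "fb_sort":
        keys = experiment._keys().values
        order = np.lexsort((keys, -fb))
        return {"order": order, "fraction_bound": fb, "labels": None}
    if mode == "hierarchical":
        if experiment.n_cells < 2:
            raise ValueError("hierarchical ordering needs at least 2 cells")
        linkage = hierarchy.ward(experiment.spectra)
        order = hierarchy.leaves_list(linkage)
        labels = None
        if n_clusters is not None:
            labels = hierarchy.fcluster(linkage, t=n_clusters, criterion="maxclust")
        return {"order": order, "fraction_bound": fb, "labels": labels, "linkage": linkage}
    raise ValueError(f"unknown ordering mode {mode!r}")


def correlate_fb_feature(experiment: ExperimentSet, feature: str) -> CorrelationResult:
    """Pearson correlation of per-cell FB with a morphology/intensity feature.

    Cells with undefined feature values are dropped (logged); a zero-variance
    feature yields an undefined result rather than an error.
    """
    if feature not in experiment.cells.columns:
        raise ValueError(f"unknown feature {feature!r}")
    fb = experiment.cells["fraction_bound"].values.astype(float)
    x = experiment.cells[feature].values.astype(float)
    ok = np.isfinite(x) & np.isfinite(fb)
    n_dropped = int((~ok).sum())
    if n_dropped:
        logger.info("%d cells dropped with undefined %s", n_dropped, feature)
    x, fb = x[ok], fb[ok]
    if x.size < 3:
        raise ValueError(f"feature {feature!r} defined for fewer than 3 cells")
    if np.ptp(x) == 0 or np.ptp(fb) == 0:
        return CorrelationResult(np.nan, np.nan, np.nan, np.nan, int(x.size), defined=False)
    lin = stats.linregress(x, fb)
    return CorrelationResult(
        R=float(lin.rvalue),
        p=float(lin.pvalue),
        slope=float(lin.slope),
        intercept=float(lin.intercept),
        n=int(x.size),
    )


def significance_stars(p: float) -> str:
    """Conventional alpha ladder: * <=0.05, ** <=0.01, *** <=0.001, **** <=0.0001."""
    if p <= 1e-4:
        return "****"
    if p <= 1e-3:
        return "***"
    if p <= 1e-2:
        return "**"
    if p <= 0.05:
        return "*"
    return "ns"
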