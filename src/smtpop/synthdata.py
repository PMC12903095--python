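"""Ground-truth-labeled synthetic fast-SMT datasets.

Emulates the acquisition this pipeline analyzes: sparse single-molecule
trajectories of a nuclear transcription factor recorded at high frame rate in
a monolayer of cells.  Each molecule occupies one of a small set of diffusive
states (from immobile, D ~ 0.01 um^2/s, to freely diffusing, D ~ 10 um^2/s),
moves by 2D Brownian motion confined to a nuclear disk, and is observed with
Gaussian localization error.  Track length is photobleaching-limited
(geometric) and additionally truncated when the molecule's 3D z-walk first
leaves the axial detection slab.  Populations of cells carry per-cell
heterogeneity in bound fraction, bimodal marker intensities with morphology
covariates, and optional DR/PAPA illumination classes with oligomer-enriched
PAPA trajectories.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .acquisition import AcquisitionParams

logger = logging.getLogger(__name__)

TRAJECTORY_COLUMNS = ["fov_id", "cell_id", "trajectory_id", "frame", "x_um", "y_um", "class"]


# ---------------------------------------------------------------------------
# Domain types


@dataclass(frozen=True)
class MotionState:
    """One diffusive state: a name, a coefficient (um^2/s) and an occupancy weight."""

    name: str
    D: float
    weight: float

    def __post_init__(self) -> None:
        if self.D < 0:
            raise ValueError(f"MotionState.D must be >= 0, got {self.D!r}")
        if not 0 <= self.weight <= 1:
            raise ValueError(f"MotionState.weight must lie in [0, 1], got {self.weight!r}")


def validate_states(states: list[MotionState]) -> None:
    if not states:
        raise ValueError("state set must be nonempty")
    total = sum(s.weight for s in states)
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"state weights must sum to 1 within 1e-9, got {total!r}")


def two_state_mixture(fraction_bound: float, d_bound: float = 0.01, d_free: float = 5.0) -> list[MotionState]:
    """Bound/free two-state mixture with the given bound-state weight."""
    if not 0 <= fraction_bound <= 1:
        raise ValueError(f"fraction_bound must lie in [0, 1], got {fraction_bound!r}")
    return [
        MotionState("bound", d_bound, fraction_bound),
        MotionState("free", d_free, 1.0 - fraction_bound),
    ]


@dataclass
class CellSpec:
    """Everything needed to simulate one cell's trajectories."""

    cell_id: object
    states: list[MotionState]
    n_trajectories: int
    marker_class: str = "unassigned"  # {positive, negative, unassigned}
    marker_intensity_mean: float = 0.0
    tf_intensity_mean: float = 0.0
    nucleus_center: tuple[float, float] = (0.0, 0.0)
    nucleus_radius: float = 4.0
    fov_id: object = 0

    def validate(self) -> None:
        validate_states(self.states)
        if self.n_trajectories < 0:
            raise ValueError(f"CellSpec.n_trajectories must be >= 0, got {self.n_trajectories!r}")
        if not self.nucleus_radius > 0:
            raise ValueError(f"CellSpec.nucleus_radius must be > 0, got {self.nucleus_radius!r}")

    @property
    def true_fraction_bound(self) -> float:
        """Occupation mass of states below the immobile threshold (0.15 um^2/s)."""
        return sum(s.weight for s in self.states if s.D < 0.15)


@dataclass
class GroundTruth:
    """Per-cell and per-trajectory truth tables of a synthetic dataset."""

    cells: pd.DataFrame          # cell_id, fov_id, true_fb, marker_class, nucleus geometry
    trajectories: pd.DataFrame   # cell_id, trajectory_id, D, state, oligomer, class


@dataclass
class SyntheticDataset:
    """Trajectories plus the cell table skeleton and ground truth."""

    trajectories: pd.DataFrame
    cells: pd.DataFrame
    ground_truth: GroundTruth
    acq: AcquisitionParams
    fov_size: float = 60.0  # um, square field


# ---------------------------------------------------------------------------
# Single-cell trajectory simulation


def _survive_substep(rng, z0, z1, D, dt_sub, dz):
    """Brownian-bridge survival between two in-slab endpoints.

    The probability that the path crossed an absorbing boundary between two
    sampled in-slab positions is ``exp(-z0*z1/(D*dt))`` per boundary (level 0;
    mirrored for level dz); double crossings are neglected, which is accurate
    once the per-substep step is small against dz.
    """
    var = D * dt_sub  # per-axis Brownian variance over the substep is 2*D*dt_sub
    p_cross_lo = np.exp(-z0 * z1 / var)
    p_cross_hi = np.exp(-(dz - z0) * (dz - z1) / var)
    p_survive = (1.0 - p_cross_lo) * (1.0 - p_cross_hi)
    return rng.random(z0.shape) < p_survive


def _slab_lengths(rng, n, D, dz, dt, max_frames, substeps=4):
    """Number of localizations before first axial exit, capped at max_frames."""
    if D == 0:
        return np.full(n, max_frames, dtype=np.int64)
    z = rng.uniform(0.0, dz, size=n)
    alive = np.ones(n, dtype=bool)
    lengths = np.full(n, max_frames, dtype=np.int64)
    dt_sub = dt / substeps
    step_sd = np.sqrt(2.0 * D * dt_sub)
    for frame in range(1, max_frames):
        idx = np.flatnonzero(alive)
        if idx.size == 0:
            break
        z_alive = z[idx]
        ok = np.ones(idx.size, dtype=bool)
        for _ in range(substeps):
            z_new = z_alive + step_sd * rng.standard_normal(idx.size)
            inside = (z_new > 0) & (z_new < dz)
            bridge = np.zeros(idx.size, dtype=bool)
            if inside.any():
                bridge[inside] = _survive_substep(
                    rng, z_alive[inside], z_new[inside], D, dt_sub, dz
                )
            ok &= inside & bridge
            z_alive = np.where(ok, z_new, z_alive)
        died = ~ok
        if died.any():
            lengths[idx[died]] = frame
            alive[idx[died]] = False
        z[idx] = z_alive
    return lengths


def _reflect_disk(x, y, center, radius):
    """Radial fold-back of positions outside the nuclear disk."""
    dx = x - center[0]
    dy = y - center[1]
    r = np.hypot(dx, dy)
    outside = r > radius
    if outside.any():
        r_out = r[outside]
        r_new = np.maximum(2.0 * radius - r_out, 0.0)
        scale = np.where(r_out > 0, r_new / r_out, 0.0)
        x[outside] = center[0] + dx[outside] * scale
        y[outside] = center[1] + dy[outside] * scale
    return x, y


def simulate_cell_trajectories(
    spec: CellSpec,
    acq: AcquisitionParams,
    seed,
    *,
    bleaching: bool = True,
    axial_truncation: bool = True,
    movie_length: int | None = None,
    fixed_length: int | None = None,
    max_track_len: int = 200,
    substeps: int = 4,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate one cell's trajectories; deterministic given the seed.

    Each trajectory draws a state by the spec's weights, a bleaching length
    (geometric with mean ``acq.mean_track_len``), an axial-slab first-exit
    length, and a start frame; observed positions are the true Brownian path
    plus per-axis Gaussian localization error.  Trajectories shorter than 2
    localizations are discarded.

    Returns
    -------
    (trajectories, truth):
        trajectory table with columns ``fov_id, cell_id, trajectory_id, frame,
        x_um, y_um, class`` and a per-trajectory truth table with the assigned
        state and coefficient.
    """
    spec.validate()
    rng = np.random.default_rng(seed)
    n = spec.n_trajectories
    if n == 0:
        empty = pd.DataFrame(columns=TRAJECTORY_COLUMNS)
        truth = pd.DataFrame(columns=["cell_id", "trajectory_id", "D", "state"])
        return empty, truth

    weights = np.array([s.weight for s in spec.states])
    state_idx = rng.choice(len(spec.states), size=n, p=weights / weights.sum())
    d_values = np.array([s.D for s in spec.states])[state_idx]

    if fixed_length is not None:
        lengths = np.full(n, int(fixed_length), dtype=np.int64)
    else:
        cap = max_track_len if movie_length is None else min(max_track_len, movie_length)
        if bleaching:
            lengths = rng.geometric(1.0 / acq.mean_track_len, size=n).astype(np.int64)
            lengths = np.minimum(lengths, cap)
        else:
            lengths = np.full(n, cap, dtype=np.int64)
        if axial_truncation:
            for s_i, state in enumerate(spec.states):
                mask = state_idx == s_i
                if not mask.any() or state.D == 0:
                    continue
                state_cap = int(lengths[mask].max())
                slab = _slab_lengths(rng, int(mask.sum()), state.D, acq.dz, acq.dt, state_cap, substeps)
                lengths[mask] = np.minimum(lengths[mask], slab)

    movie = movie_length if movie_length is not None else 10_000
    starts = rng.integers(0, max(1, movie - 1), size=n)

    keep = lengths >= 2
    rows_x, rows_y, rows_frame, rows_tid = [], [], [], []
    kept_ids = np.flatnonzero(keep)
    for tid in kept_ids:
        L = int(lengths[tid])
        D = d_values[tid]
        step_sd = np.sqrt(2.0 * D * acq.dt)
        r0 = spec.nucleus_radius * np.sqrt(rng.random())
        theta = rng.uniform(0, 2 * np.pi)
        x = np.empty(L)
        y = np.empty(L)
        x[0] = spec.nucleus_center[0] + r0 * np.cos(theta)
        y[0] = spec.nucleus_center[1] + r0 * np.sin(theta)
        if D > 0:
            dx = step_sd * rng.standard_normal(L - 1)
            dy = step_sd * rng.standard_normal(L - 1)
            x[1:] = x[0] + np.cumsum(dx)
            y[1:] = y[0] + np.cumsum(dy)
            x, y = _reflect_disk(x, y, spec.nucleus_center, spec.nucleus_radius)
        else:
            x[1:] = x[0]
            y[1:] = y[0]
        if acq.sigma_loc > 0:
            x = x + acq.sigma_loc * rng.standard_normal(L)
            y = y + acq.sigma_loc * rng.standard_normal(L)
        rows_x.append(x)
        rows_y.append(y)
        rows_frame.append(starts[tid] + np.arange(L))
        rows_tid.append(np.full(L, tid))

    if not rows_x:
        trajectories = pd.DataFrame(columns=TRAJECTORY_COLUMNS)
    else:
        trajectories = pd.DataFrame(
            {
                "fov_id": spec.fov_id,
                "cell_id": spec.cell_id,
                "trajectory_id": np.concatenate(rows_tid),
                "frame": np.concatenate(rows_frame).astype(np.int64),
                "x_um": np.concatenate(rows_x),
                "y_um": np.concatenate(rows_y),
                "class": "DR",
            }
        )[TRAJECTORY_COLUMNS]
    truth = pd.DataFrame(
        {
            "cell_id": spec.cell_id,
            "trajectory_id": kept_ids,
            "D": d_values[kept_ids],
            "state": [spec.states[i].name for i in state_idx[kept_ids]],
        }
    )
    return trajectories, truth


# ---------------------------------------------------------------------------
# Population simulation


@dataclass
class MarkerModel:
    """Bimodal marker-intensity model with class-linked morphology."""

    positive_fraction: float = 0.25
    positive_intensity: float = 1000.0
    negative_intensity: float = 100.0
    intensity_sd: float = 50.0
    # positive (stem-like) cells are smaller and closer together
    positive_radius: float = 3.2
    negative_radius: float = 4.2
    radius_sd: float = 0.3


@dataclass
class PopulationConfig:
    """Study-condition parameters of a simulated cell population.

    Defaults emulate the budding-organoid condition: per-cell bound fraction
    drawn around 0.40 (SD 0.05), a bound state at 0.01 um^2/s and a free state
    at 5 um^2/s, ~300 trajectories per cell, and a quarter of cells
    marker-positive with higher bound fraction when ``class_fb`` is set.
    """

    n_cells: int = 150
    n_trajectories: int = 300
    fb_mean: float = 0.40
    fb_sd: float = 0.05
    d_bound: float = 0.01
    d_free: float = 5.0
    class_fb: dict | None = None       # e.g. {"positive": 0.48, "negative": 0.38}
    marker: MarkerModel = field(default_factory=MarkerModel)
    use_marker: bool = False
    cells_per_fov: int = 25
    fov_size: float = 60.0
    movie_length: int = 10_000
    max_track_len: int = 200
    tf_intensity_mean: float = 500.0
    tf_intensity_sd: float = 120.0


def _truncated_normal(rng, mean, sd, size, lo=0.0, hi=1.0):
    mean = np.broadcast_to(np.asarray(mean, dtype=float), (size,))
    out = rng.normal(mean, sd, size=size)
    bad = (out < lo) | (out > hi)
    while bad.any():
        out[bad] = rng.normal(mean[bad], sd)
        bad = (out < lo) | (out > hi)
    return out


def _place_nuclei(rng, n, fov_size, radii, max_tries=2000):
    """Random nonoverlapping-ish centers; falls back to jittered grid placement."""
    centers = []
    for i in range(n):
        r = radii[i]
        for _ in range(max_tries):
            c = rng.uniform(r, fov_size - r, size=2)
            if all(np.hypot(*(c - o)) > (r + ro) * 0.9 for o, ro in zip(centers, radii)):
                centers.append(c)
                break
        else:
            centers.append(rng.uniform(r, fov_size - r, size=2))
    return np.array(centers)


def build_cell_specs(config: PopulationConfig, seed) -> list[CellSpec]:
    """Draw per-cell state mixtures, marker classes and nuclear geometry."""
    rng = np.random.default_rng(seed)
    n = config.n_cells
    marker = config.marker
    if config.use_marker:
        positive = rng.random(n) < marker.positive_fraction
    else:
        positive = np.zeros(n, dtype=bool)
    if config.class_fb is not None:
        fb_mean = np.where(
            positive, config.class_fb["positive"], config.class_fb["negative"]
        )
    else:
        fb_mean = np.full(n, config.fb_mean)
    fb = _truncated_normal(rng, fb_mean, config.fb_sd, n)
    radii = np.clip(
        rng.normal(
            np.where(positive, marker.positive_radius, marker.negative_radius),
            marker.radius_sd,
        ),
        1.5,
        None,
    )
    marker_int = np.clip(
        rng.normal(
            np.where(positive, marker.positive_intensity, marker.negative_intensity),
            marker.intensity_sd,
        ),
        1.0,
        None,
    )
    tf_int = np.clip(rng.normal(config.tf_intensity_mean, config.tf_intensity_sd, n), 1.0, None)

    specs = []
    n_fovs = int(np.ceil(n / config.cells_per_fov)) if n else 0
    for fov in range(n_fovs):
        lo = fov * config.cells_per_fov
        hi = min(lo + config.cells_per_fov, n)
        centers = _place_nuclei(rng, hi - lo, config.fov_size, radii[lo:hi])
        for j, i in enumerate(range(lo, hi)):
            specs.append(
                CellSpec(
                    cell_id=i,
                    states=two_state_mixture(float(fb[i]), config.d_bound, config.d_free),
                    n_trajectories=config.n_trajectories,
                    marker_class="positive" if positive[i] else "negative",
                    marker_intensity_mean=float(marker_int[i]),
                    tf_intensity_mean=float(tf_int[i]),
                    nucleus_center=tuple(centers[j]),
                    nucleus_radius=float(radii[i]),
                    fov_id=fov,
                )
            )
    return specs


def simulate_population(config: PopulationConfig, acq: AcquisitionParams, seed) -> SyntheticDataset:
    """Simulate a whole multi-FOV cell population with ground truth.

    Zero cells or zero trajectories yield an explicit empty dataset.
    """
    rng = np.random.default_rng(seed)
    specs = build_cell_specs(config, rng.integers(2**31))
    traj_frames, truth_frames = [], []
    for spec in specs:
        t, gt = simulate_cell_trajectories(
            spec,
            acq,
            int(rng.integers(2**31)),
            movie_length=config.movie_length,
            max_track_len=config.max_track_len,
        )
        traj_frames.append(t)
        truth_frames.append(gt)

    trajectories = (
        pd.concat(traj_frames, ignore_index=True)
        if traj_frames
        else pd.DataFrame(columns=TRAJECTORY_COLUMNS)
    )
    traj_truth = (
        pd.concat(truth_frames, ignore_index=True)
        if truth_frames
        else pd.DataFrame(columns=["cell_id", "trajectory_id", "D", "state"])
    )
    traj_truth["oligomer"] = False
    traj_truth["class"] = "DR"

    cells = pd.DataFrame(
        {
            "cell_id": [s.cell_id for s in specs],
            "fov_id": [s.fov_id for s in specs],
            "marker_class": [s.marker_class if config.use_marker else "unassigned" for s in specs],
            "marker_intensity": [s.marker_intensity_mean for s in specs],
            "tf_intensity": [s.tf_intensity_mean for s in specs],
            "nucleus_x": [s.nucleus_center[0] for s in specs],
            "nucleus_y": [s.nucleus_center[1] for s in specs],
            "nucleus_radius": [s.nucleus_radius for s in specs],
        }
    )
    truth_cells = cells[["cell_id", "fov_id", "nucleus_x", "nucleus_y", "nucleus_radius"]].copy()
    truth_cells["true_fb"] = [s.true_fraction_bound for s in specs]
    truth_cells["marker_class"] = [s.marker_class for s in specs]
    logger.info(
        "simulated %d cells, %d trajectories, %d localizations",
        len(specs),
        traj_truth.shape[0],
        trajectories.shape[0],
    )
    return SyntheticDataset(
        trajectories=trajectories,
        cells=cells,
        ground_truth=GroundTruth(cells=truth_cells, trajectories=traj_truth),
        acq=acq,
        fov_size=config.fov_size,
    )


# ---------------------------------------------------------------------------
# PAPA class assignment


@dataclass
class PapaDesign:
    """Two-subpopulation (oligomer/monomer) design for DR/PAPA simulations."""

    oligomer_fraction: float = 0.35
    oligomer_fb: float = 0.8
    monomer_fb: float = 0.3
    enrichment: float = 1.0
    nonspecific_rate: float = 0.0
    papa_share: float = 0.4

    @classmethod
    def from_class_fb(
        cls,
        fb_dr: float,
        fb_papa: float,
        papa_share: float = 0.4,
        oligomer_fraction: float = 0.35,
        oligomer_fb: float = 0.8,
    ) -> "PapaDesign":
        """Solve monomer FB and enrichment to hit target class bound fractions.

        The overall FB is the class-share-weighted mean; the enrichment factor
        follows from requiring the PAPA class (oligomer-enriched mixture) to
        have the target FB.
        """
        f_o = oligomer_fraction
        f_m = 1.0 - f_o
        overall = (1.0 - papa_share) * fb_dr + papa_share * fb_papa
        monomer_fb = (overall - f_o * oligomer_fb) / f_m
        if not 0 <= monomer_fb <= 1:
            raise ValueError("infeasible design: monomer FB outside [0, 1]")
        denom = f_o * (oligomer_fb - fb_papa)
        if denom <= 0:
            raise ValueError("infeasible design: oligomer FB must exceed the PAPA-class FB")
        enrichment = f_m * (fb_papa - monomer_fb) / denom
        return cls(
            oligomer_fraction=f_o,
            oligomer_fb=oligomer_fb,
            monomer_fb=monomer_fb,
            enrichment=enrichment,
            papa_share=papa_share,
        )


def simulate_papa_population(
    config: PopulationConfig,
    design: PapaDesign,
    schedule,
    acq: AcquisitionParams,
    seed,
) -> SyntheticDataset:
    """Simulate a population whose molecules are oligomers or monomers, then
    assign DR/PAPA classes per the design and relocate tracks into the
    schedule's read windows."""
    rng = np.random.default_rng(seed)
    base = replace(config, class_fb=None, use_marker=False)
    specs = build_cell_specs(replace(base, fb_mean=design.monomer_fb, fb_sd=0.0), rng.integers(2**31))

    traj_frames, truth_frames = [], []
    for spec in specs:
        n = spec.n_trajectories
        cell_rng = np.random.default_rng(int(rng.integers(2**31)))
        oligo = cell_rng.random(n) < design.oligomer_fraction
        fb_o = float(np.clip(cell_rng.normal(design.oligomer_fb, config.fb_sd), 0, 1))
        fb_m = float(np.clip(cell_rng.normal(design.monomer_fb, config.fb_sd), 0, 1))
        for which, fb, count in (("oligomer", fb_o, int(oligo.sum())), ("monomer", fb_m, int((~oligo).sum()))):
            if count == 0:
                continue
            sub = CellSpec(
                cell_id=spec.cell_id,
                states=two_state_mixture(fb, config.d_bound, config.d_free),
                n_trajectories=count,
                nucleus_center=spec.nucleus_center,
                nucleus_radius=spec.nucleus_radius,
                fov_id=spec.fov_id,
            )
            t, gt = simulate_cell_trajectories(
                sub,
                acq,
                int(cell_rng.integers(2**31)),
                movie_length=config.movie_length,
                max_track_len=config.max_track_len,
            )
            offset = 0 if which == "oligomer" else n
            t["trajectory_id"] = t["trajectory_id"] + offset
            gt["trajectory_id"] = gt["trajectory_id"] + offset
            gt["oligomer"] = which == "oligomer"
            traj_frames.append(t)
            truth_frames.append(gt)

    trajectories = pd.concat(traj_frames, ignore_index=True)
    traj_truth = pd.concat(truth_frames, ignore_index=True)
    cells = pd.DataFrame(
        {
            "cell_id": [s.cell_id for s in specs],
            "fov_id": [s.fov_id for s in specs],
            "marker_class": "unassigned",
            "marker_intensity": [s.marker_intensity_mean for s in specs],
            "tf_intensity": [s.tf_intensity_mean for s in specs],
            "nucleus_x": [s.nucleus_center[0] for s in specs],
            "nucleus_y": [s.nucleus_center[1] for s in specs],
            "nucleus_radius": [s.nucleus_radius for s in specs],
        }
    )
    truth_cells = cells[["cell_id", "fov_id", "nucleus_x", "nucleus_y", "nucleus_radius"]].copy()
    truth_cells["true_fb"] = np.nan
    truth_cells["marker_class"] = "unassigned"
    dataset = SyntheticDataset(
        trajectories=trajectories,
        cells=cells,
        ground_truth=GroundTruth(cells=truth_cells, trajectories=traj_truth),
        acq=acq,
        fov_size=config.fov_size,
    )
    return assign_papa_classes(
        dataset,
        schedule,
        enrichment=design.enrichment,
        nonspecific_rate=design.nonspecific_rate,
        seed=int(rng.integers(2**31)),
        papa_share=design.papa_share,
    )


def assign_papa_classes(
    dataset: SyntheticDataset,
    schedule,
    enrichment: float,
    nonspecific_rate: float,
    seed,
    papa_share: float = 0.4,
) -> SyntheticDataset:
    """Label every trajectory DR or PAPA and relocate it into a read window.

    PAPA labels are drawn preferentially from the oligomer subpopulation:
    with oligomer fraction f and enrichment e, an oligomer's PAPA probability
    is ``papa_share * e / (f*e + 1-f)`` and a monomer's is
    ``papa_share / (f*e + 1-f)``; a ``nonspecific_rate`` fraction of the PAPA
    budget is assigned irrespective of oligomer state (background
    reactivation).  With enrichment=1 the two classes have identical state
    mixtures in expectation.  Each labeled trajectory is moved to a uniformly
    chosen read window of its class (truncated at the window end if needed).
    """
    from .papa import IlluminationSchedule  # local import to avoid a cycle

    if not isinstance(schedule, IlluminationSchedule):
        schedule = IlluminationSchedule(schedule)
    if not 0 <= nonspecific_rate <= 1:
        raise ValueError(f"nonspecific_rate must lie in [0, 1], got {nonspecific_rate!r}")
    if enrichment <= 0:
        raise ValueError(f"enrichment must be positive, got {enrichment!r}")
    dr_windows = schedule.windows("DR")
    papa_windows = schedule.windows("PAPA")
    if not dr_windows or not papa_windows:
        raise ValueError("schedule must contain read windows of both classes")

    rng = np.random.default_rng(seed)
    truth = dataset.ground_truth.trajectories.copy()
    oligo = truth["oligomer"].values.astype(bool)
    f = oligo.mean() if len(oligo) else 0.0
    norm = f * enrichment + (1.0 - f)
    p_specific = np.where(oligo, enrichment / norm, 1.0 / norm)
    p_papa = np.clip(papa_share * (nonspecific_rate + (1.0 - nonspecific_rate) * p_specific), 0, 1)
    is_papa = rng.random(len(truth)) < p_papa
    truth["class"] = np.where(is_papa, "PAPA", "DR")

    # relocate each trajectory (one draw per trajectory) into a read window
    # of its class
    traj = dataset.trajectories.copy()
    key = ["cell_id", "trajectory_id"]
    truth_starts = np.empty(len(truth), dtype=np.int64)
    truth_classes = truth["class"].values
    for cls, windows in (("DR", dr_windows), ("PAPA", papa_windows)):
        mask = truth_classes == cls
        n = int(mask.sum())
        if n == 0:
            continue
        widx = rng.integers(0, len(windows), size=n)
        w_start = np.array([w[0] for w in windows])[widx]
        w_end = np.array([w[1] for w in windows])[widx]
        span = np.maximum(w_end - w_start, 1)
        truth_starts[mask] = w_start + (rng.random(n) * span).astype(np.int64)
    lookup = truth.set_index(key)
    row_index = pd.MultiIndex.from_frame(traj[key])
    labels = lookup["class"].loc[row_index].values
    new_starts = pd.Series(truth_starts, index=lookup.index).loc[row_index].values
    first = traj.groupby(key, sort=False)["frame"].transform("min")
    traj["frame"] = traj["frame"].values - first.values + new_starts
    traj["class"] = labels

    # truncate at window end so tracks never span a window boundary
    window_end = np.empty(len(traj), dtype=np.int64)
    all_windows = {"DR": dr_windows, "PAPA": papa_windows}
    for cls, windows in all_windows.items():
        mask = labels == cls
        if not mask.any():
            continue
        frames = traj.loc[mask, "frame"].values
        ends = np.full(mask.sum(), -1, dtype=np.int64)
        for start, end in windows:
            inside = (frames >= start) & (frames <= end)
            ends[inside] = end
        window_end[mask] = ends
    keep = traj["frame"].values <= window_end
    traj = traj[keep].reset_index(drop=True)
    # drop remnants shorter than 2 localizations
    sizes = traj.groupby(key, sort=False)["frame"].transform("size")
    traj = traj[sizes >= 2].reset_index(drop=True)

    kept_keys = set(map(tuple, traj[key].drop_duplicates().itertuples(index=False)))
    truth = truth[[tuple(k) in kept_keys for k in truth[key].itertuples(index=False)]].reset_index(drop=True)
    return SyntheticDataset(
        trajectories=traj,
        cells=dataset.cells,
        ground_truth=GroundTruth(cells=dataset.ground_truth.cells, trajectories=truth),
        acq=dataset.acq,
        fov_size=dataset.fov_size,
    )


# ---------------------------------------------------------------------------
# Frame rendering


def render_frames(
    dataset: SyntheticDataset,
    acq: AcquisitionParams,
    *,
    image_size: int | None = None,
    psf_sigma_px: float = 1.0,
    photons: float = 500.0,
    background: float = 10.0,
    read_noise: float = 0.0,
    poisson_noise: bool = True,
    seed=0,
    frames: list[int] | None = None,
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Render localizations as Gaussian spots onto a pixel grid.

    Returns (movie [T,H,W] float, bulk_channel [H,W] float, meta).  The bulk
    channel renders filled nuclear disks at each cell's marker intensity plus
    the background, which is what nuclear segmentation consumes.  Localizations
    outside the field are clipped and counted in ``meta['n_clipped']``.
    """
    px = acq.pixel_size
    if image_size is None:
        image_size = int(np.ceil(dataset.fov_size / px))
    traj = dataset.trajectories
    if frames is None:
        frame_ids = sorted(traj["frame"].unique()) if len(traj) else []
    else:
        frame_ids = list(frames)
    rng = np.random.default_rng(seed)
    half = 4
    n_clipped = 0
    movie = np.zeros((len(frame_ids), image_size, image_size), dtype=float)
    for t_i, f in enumerate(frame_ids):
        sub = traj[traj["frame"] == f]
        img = np.full((image_size, image_size), background, dtype=float)
        for x_um, y_um in zip(sub["x_um"].values, sub["y_um"].values):
            cx = x_um / px
            cy = y_um / px
            if not (0 <= cx < image_size and 0 <= cy < image_size):
                n_clipped += 1
                continue
            x0 = int(np.floor(cx))
            y0 = int(np.floor(cy))
            xs = np.arange(max(0, x0 - half), min(image_size, x0 + half + 1))
            ys = np.arange(max(0, y0 - half), min(image_size, y0 + half + 1))
            gx = np.exp(-((xs - cx) ** 2) / (2 * psf_sigma_px**2))
            gy = np.exp(-((ys - cy) ** 2) / (2 * psf_sigma_px**2))
            spot = photons * np.outer(gy, gx) / (2 * np.pi * psf_sigma_px**2)
            img[np.ix_(ys, xs)] += spot
        if poisson_noise:
            img = rng.poisson(np.clip(img, 0, None)).astype(float)
        if read_noise > 0:
            img = img + rng.normal(0, read_noise, img.shape)
        movie[t_i] = img
    if n_clipped:
        logger.warning("%d localizations fell outside the field and were clipped", n_clipped)

    bulk = np.full((image_size, image_size), background, dtype=float)
    yy, xx = np.mgrid[0:image_size, 0:image_size]
    for _, cell in dataset.cells.iterrows():
        cx = cell["nucleus_x"] / px
        cy = cell["nucleus_y"] / px
        rad = cell["nucleus_radius"] / px
        disk = (xx - cx) ** 2 + (yy - cy) ** 2 <= rad**2
        bulk[disk] += cell["marker_intensity"]
    meta = {
        "pixel_size": px,
        "image_size": image_size,
        "frames": frame_ids,
        "n_clipped": n_clipped,
        "psf_sigma_px": psf_sigma_px,
    }
    return movie, bulk, meta
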