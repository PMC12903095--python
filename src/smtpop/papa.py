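"""DR/PAPA trajectory classing and bound-fraction comparison.

In proximity-assisted photoactivation (PAPA) SMT, a shelved receiver
fluorophore is reactivated either directly by a violet pulse (DR), sampling
the whole receiver population, or by a green pulse only when a labeled sender
is nearby (PAPA), selecting trajectories of self-associated molecules.  The
acquisition alternates pulse types, and each pulse is followed by a read
window; a trajectory's class is the class of the read window containing its
first localization.  Bound fractions of the two classes are then inferred
per cell and compared with a cell-level bootstrap and permutation test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .acquisition import AcquisitionParams
from .spectra import (
    DEFAULT_FB_THRESHOLD,
    DiffusionGrid,
    InferenceOptions,
    extract_jumps,
    infer_spectra,
)

logger = logging.getLogger(__name__)

PULSE_TYPES = {"DR": "violet_405", "PAPA": "green_561"}


@dataclass(frozen=True)
class Cycle:
    """One illumination cycle: a reactivation pulse and its read window."""

    pulse_type: str              # "DR" (violet 405 nm) or "PAPA" (green 561 nm)
    pulse_frame: int
    read_start: int
    read_end: int                # inclusive

    def __post_init__(self) -> None:
        if self.pulse_type not in PULSE_TYPES:
            raise ValueError(f"pulse_type must be one of {sorted(PULSE_TYPES)}, got {self.pulse_type!r}")
        if not self.pulse_frame <= self.read_start <= self.read_end:
            raise ValueError("read window must follow its pulse and be nonempty")


@dataclass
class IlluminationSchedule:
    """Ordered DR/PAPA cycles with disjoint read windows."""

    cycles: list[Cycle]

    def __post_init__(self) -> None:
        if not self.cycles:
            raise ValueError("schedule needs at least one cycle")
        windows = sorted((c.read_start, c.read_end) for c in self.cycles)
        for (s1, e1), (s2, e2) in zip(windows, windows[1:]):
            if s2 <= e1:
                raise ValueError(f"read windows overlap: [{s1},{e1}] and [{s2},{e2}]")

    def windows(self, pulse_type: str) -> list[tuple[int, int]]:
        return [(c.read_start, c.read_end) for c in self.cycles if c.pulse_type == pulse_type]

    @classmethod
    def alternating(
        cls,
        n_cycles: int = 100,
        frames_per_window: int = 14,
        dead_frames: int = 1,
        start: int = 0,
    ) -> "IlluminationSchedule":
        """DR/PAPA cycles alternating back-to-back (DR first)."""
        cycles = []
        f = start
        for i in range(n_cycles):
            pulse = "DR" if i % 2 == 0 else "PAPA"
            cycles.append(
                Cycle(
                    pulse_type=pulse,
                    pulse_frame=f,
                    read_start=f + dead_frames,
                    read_end=f + dead_frames + frames_per_window - 1,
                )
            )
            f += dead_frames + frames_per_window
        return cls(cycles)


@dataclass
class PapaComparison:
    """Bound fractions of DR vs PAPA trajectory classes with uncertainty."""

    fb_dr: float
    fb_dr_ci: tuple[float, float]
    fb_papa: float
    fb_papa_ci: tuple[float, float]
    delta: float                 # FB_PAPA - FB_DR
    p: float
    n_cells: int
    n_trajectories: dict
    paired: bool


def split_by_schedule(
    trajectories: pd.DataFrame, schedule: IlluminationSchedule
) -> tuple[pd.DataFrame, pd.DataFrame, int]:
    """Partition trajectories into DR and PAPA sets by their first in-window
    localization.

    Trajectories spanning a window boundary are truncated at the boundary
    (remnants shorter than 2 localizations are dropped and counted);
    trajectories starting outside all read windows are unassigned.

    Returns (DR table, PAPA table, unassigned count).
    """
    key = ["fov_id", "cell_id", "trajectory_id"] if "fov_id" in trajectories.columns else [
        "cell_id",
        "trajectory_id",
    ]
    first = trajectories.groupby(key, sort=False)["frame"].transform("min")
    frames = trajectories["frame"].values
    first_frames = first.values
    labels = np.full(len(trajectories), "", dtype=object)
    window_end = np.full(len(trajectories), -1, dtype=np.int64)
    for cls in ("DR", "PAPA"):
        for start, end in schedule.windows(cls):
            inside = (first_frames >= start) & (first_frames <= end)
            labels[inside] = cls
            window_end[inside] = end
    assigned = labels != ""
    n_unassigned = int(
        trajectories[~assigned].groupby(key, sort=False).ngroups if (~assigned).any() else 0
    )
    out = trajectories[assigned].copy()
    out["class"] = labels[assigned]
    # truncate at the window boundary
    out = out[out["frame"].values <= window_end[assigned]]
    sizes = out.groupby(key, sort=False)["frame"].transform("size")
    n_dropped = int(out[sizes < 2].groupby(key, sort=False).ngroups if (sizes < 2).any() else 0)
    if n_dropped:
        logger.info("%d truncated remnants (<2 localizations) dropped", n_dropped)
    out = out[sizes >= 2]
    dr = out[out["class"] == "DR"].reset_index(drop=True)
    papa = out[out["class"] == "PAPA"].reset_index(drop=True)
    return dr, papa, n_unassigned


def papa_compare(
    dr_trajectories: pd.DataFrame,
    papa_trajectories: pd.DataFrame,
    acq: AcquisitionParams,
    grid: DiffusionGrid | None = None,
    options: InferenceOptions | None = None,
    B: int = 1000,
    seed: int = 0,
    n_permutations: int = 20_000,
    fb_threshold: float = DEFAULT_FB_THRESHOLD,
    min_jumps_per_class: int | None = None,
) -> PapaComparison:
    """Infer per-cell spectra for each class and compare bound fractions.

    Bound fractions are bootstrapped over cells per class.  The p-value is a
    permutation test: when both classes are present in the same cells
    (the paired design of a PAPA acquisition), per-cell class labels are
    swapped (sign flips of per-cell deltas); otherwise group labels are
    permuted across cells.  Deterministic given the seed.
    """
    if len(dr_trajectories) == 0 or len(papa_trajectories) == 0:
        raise ValueError("both DR and PAPA classes must be nonempty")
    grid = grid or DiffusionGrid.default()
    options = options or InferenceOptions()
    if min_jumps_per_class is not None:
        from dataclasses import replace

        options = replace(options, min_jumps=min_jumps_per_class)
    fb_by_class = {}
    n_traj = {}
    for name, table in (("DR", dr_trajectories), ("PAPA", papa_trajectories)):
        jumps = extract_jumps(table, acq)
        spectra, excluded = infer_spectra(jumps, grid, acq, options)
        below = grid.values < fb_threshold
        fb_by_class[name] = {
            s.cell_id: float(s.occupations[below].sum()) for s in spectra
        }
        key = ["cell_id", "trajectory_id"]
        n_traj[name] = int(table[key].drop_duplicates().shape[0])
        if excluded:
            logger.info("%s class: %d cells below the jump QC gate", name, len(excluded))

    common = sorted(set(fb_by_class["DR"]) & set(fb_by_class["PAPA"]), key=str)
    paired = len(common) >= 3
    rng = np.random.default_rng(seed)
    if paired:
        fb_dr = np.array([fb_by_class["DR"][c] for c in common])
        fb_papa = np.array([fb_by_class["PAPA"][c] for c in common])
        n_cells = len(common)
    else:
        fb_dr = np.array(sorted(fb_by_class["DR"].values()))
        fb_papa = np.array(sorted(fb_by_class["PAPA"].values()))
        n_cells = len(fb_dr) + len(fb_papa)
    if min(len(fb_dr), len(fb_papa)) < 3:
        raise ValueError("each class needs at least 3 cells passing QC")

    def boot_ci(values: np.ndarray) -> tuple[float, float]:
        idx = rng.integers(0, values.size, size=(B, values.size))
        reps = values[idx].mean(axis=1)
        lo, hi = np.percentile(reps, [2.5, 97.5])
        return float(lo), float(hi)

    ci_dr = boot_ci(fb_dr)
    ci_papa = boot_ci(fb_papa)
    delta = float(fb_papa.mean() - fb_dr.mean())

    if paired:
        diffs = fb_papa - fb_dr
        signs = rng.choice([-1.0, 1.0], size=(n_permutations, diffs.size))
        null = (signs * diffs[None, :]).mean(axis=1)
        p = float((np.sum(np.abs(null) >= abs(delta) - 1e-15) + 1) / (n_permutations + 1))
    else:
        pooled = np.concatenate([fb_papa, fb_dr])
        n_p = fb_papa.size
        count = 0
        for _ in range(n_permutations):
            rng.shuffle(pooled)
            if abs(pooled[:n_p].mean() - pooled[n_p:].mean()) >= abs(delta) - 1e-15:
                count += 1
        p = float((count + 1) / (n_permutations + 1))

    return PapaComparison(
        fb_dr=float(fb_dr.mean()),
        fb_dr_ci=ci_dr,
        fb_papa=float(fb_papa.mean()),
        fb_papa_ci=ci_papa,
        delta=delta,
        p=p,
        n_cells=n_cells,
        n_trajectories=n_traj,
        paired=paired,
    )
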