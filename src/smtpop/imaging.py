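"""Spot detection, trajectory linking, nuclear segmentation and cell features.

The imaging stages mirror a standard automated fast-SMT acquisition: spots in
each sparse-labeling frame are detected by a Laplacian-of-Gaussian filter and
refined to subpixel centers by local centroid fitting; detections are linked
frame-to-frame into trajectories by greedy nearest-neighbor assignment;
nuclei are segmented from a bulk-labeled channel (Otsu threshold, hole
filling, watershed splitting of touching nuclei, size filter); per-cell
morphology and intensity features feed the downstream marker classification
and correlation analyses.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy.spatial.distance import cdist
from skimage.feature import blob_log, peak_local_max
from skimage.filters import threshold_otsu
from skimage.measure import regionprops
from skimage.segmentation import watershed

logger = logging.getLogger(__name__)


@dataclass
class DetectionParams:
    """Band-pass scale and threshold of the LoG spot detector (pixel units)."""

    sigma_px: float = 1.0       # expected PSF sigma
    threshold: float = 0.5      # absolute LoG response threshold
    refine_radius: int = 2      # half-width of the centroid-refinement window


@dataclass
class SegmentationParams:
    min_area_px: int = 50
    max_area_px: int = 100_000
    smoothing_sigma_px: float = 2.0
    watershed_footprint_px: int = 15  # min peak separation when splitting


# ---------------------------------------------------------------------------
# Spot detection


def detect_spots(frame_image: np.ndarray, params: DetectionParams | None = None, pixel_size: float = 1.0,
                 fov_id=0, frame: int = 0) -> pd.DataFrame:
    """Detect single-molecule spots in one frame.

    LoG blob candidates are refined to subpixel centers by background-
    subtracted centroid fitting in a small window.  Returns a table with
    columns ``frame, x_um, y_um, x_px, y_px, intensity, fov_id`` (possibly
    empty).  Deterministic.
    """
    params = params or DetectionParams()
    image = np.asarray(frame_image, dtype=float)
    if image.ndim != 2:
        raise ValueError(f"detect_spots expects a 2D image, got ndim={image.ndim}")
    blobs = blob_log(
        image,
        min_sigma=params.sigma_px * 0.8,
        max_sigma=params.sigma_px * 1.6,
        num_sigma=3,
        threshold=params.threshold,
    )
    rows = []
    r = params.refine_radius
    h, w = image.shape
    for by, bx, _sigma in blobs:
        y0, x0 = int(round(by)), int(round(bx))
        ys = slice(max(0, y0 - r), min(h, y0 + r + 1))
        xs = slice(max(0, x0 - r), min(w, x0 + r + 1))
        window = image[ys, xs]
        base = window.min()
        weights = np.clip(window - base, 0, None)
        total = weights.sum()
        if total <= 0:
            cy, cx = float(y0), float(x0)
        else:
            yy, xx = np.mgrid[ys, xs]
            cy = float((weights * yy).sum() / total)
            cx = float((weights * xx).sum() / total)
        rows.append((frame, cx * pixel_size, cy * pixel_size, cx, cy, float(window.sum()), fov_id))
    return pd.DataFrame(rows, columns=["frame", "x_um", "y_um", "x_px", "y_px", "intensity", "fov_id"])


def detect_movie(movie: np.ndarray, params: DetectionParams | None = None, pixel_size: float = 1.0,
                 fov_id=0, frame_ids=None) -> pd.DataFrame:
    """Run :func:`detect_spots` over every frame of a movie stack."""
    frames = []
    ids = frame_ids if frame_ids is not None else range(movie.shape[0])
    for t, frame_id in zip(range(movie.shape[0]), ids):
        frames.append(detect_spots(movie[t], params, pixel_size, fov_id=fov_id, frame=frame_id))
    if not frames:
        return pd.DataFrame(columns=["frame", "x_um", "y_um", "x_px", "y_px", "intensity", "fov_id"])
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# Linking


def link_localizations(localizations: pd.DataFrame, max_radius: float, max_gap: int = 0) -> pd.DataFrame:
    """Greedy nearest-neighbor frame-to-frame linking.

    Candidate links within ``max_radius`` (um) are assigned in order of
    increasing distance, ties broken by lower trajectory id; each localization
    joins at most one trajectory.  Gaps up to ``max_gap`` frames are allowed
    (no interpolated positions).  Returns the localization table with a
    ``trajectory_id`` column.
    """
    if max_radius < 0:
        raise ValueError(f"max_radius must be >= 0, got {max_radius!r}")
    if max_gap < 0:
        raise ValueError(f"max_gap must be >= 0, got {max_gap!r}")
    locs = localizations.sort_values(["frame"], kind="mergesort").reset_index(drop=True)
    n = len(locs)
    traj_id = np.full(n, -1, dtype=np.int64)
    next_id = 0
    # open trajectories: trajectory_id -> (row index of last point, last frame)
    open_tracks: dict[int, int] = {}
    frames = locs["frame"].values
    xy = locs[["x_um", "y_um"]].values
    for f in np.unique(frames):
        idx = np.flatnonzero(frames == f)
        # candidate open tracks whose last frame is within the gap window
        cand = [(tid, last) for tid, last in open_tracks.items() if 1 <= f - frames[last] <= max_gap + 1]
        if cand and idx.size:
            last_rows = np.array([last for _, last in cand])
            d = cdist(xy[last_rows], xy[idx])
            pairs = [
                (d[i, j], cand[i][0], i, j)
                for i in range(len(cand))
                for j in range(idx.size)
                if d[i, j] <= max_radius
            ]
            pairs.sort(key=lambda p: (p[0], p[1]))
            used_tracks: set[int] = set()
            used_points: set[int] = set()
            for dist, tid, i, j in pairs:
                if tid in used_tracks or j in used_points:
                    continue
                traj_id[idx[j]] = tid
                open_tracks[tid] = idx[j]
                used_tracks.add(tid)
                used_points.add(j)
        # new trajectories for unassigned detections
        for j in idx:
            if traj_id[j] == -1:
                traj_id[j] = next_id
                open_tracks[next_id] = j
                next_id += 1
        # close stale tracks
        stale = [tid for tid, last in open_tracks.items() if f - frames[last] > max_gap]
        for tid in stale:
            del open_tracks[tid]
    locs = locs.copy()
    locs["trajectory_id"] = traj_id
    return locs


# ---------------------------------------------------------------------------
# Segmentation and features


def segment_nuclei(bulk_image: np.ndarray, params: SegmentationParams | None = None) -> np.ndarray:
    """Segment nuclei from the bulk-labeled channel.

    Otsu threshold -> hole filling -> distance-transform watershed to split
    touching nuclei -> size filter.  An all-background image yields an empty
    (all-zero) label mask, not an error.
    """
    params = params or SegmentationParams()
    image = np.asarray(bulk_image, dtype=float)
    if image.ndim != 2:
        raise ValueError(f"segment_nuclei expects a 2D image, got ndim={image.ndim}")
    smoothed = ndi.gaussian_filter(image, params.smoothing_sigma_px)
    if np.ptp(smoothed) == 0:
        return np.zeros(image.shape, dtype=np.int32)
    thr = threshold_otsu(smoothed)
    mask = smoothed > thr
    mask = ndi.binary_fill_holes(mask)
    if not mask.any():
        return np.zeros(image.shape, dtype=np.int32)
    distance = ndi.distance_transform_edt(mask)
    peaks = peak_local_max(
        distance,
        labels=mask,
        min_distance=params.watershed_footprint_px,
        exclude_border=False,
    )
    markers = np.zeros(image.shape, dtype=np.int32)
    for i, (y, x) in enumerate(peaks, start=1):
        markers[y, x] = i
    if markers.max() == 0:
        labels, _ = ndi.label(mask)
    else:
        labels = watershed(-distance, markers, mask=mask)
    # size filter, then relabel to contiguous positive integers
    out = np.zeros_like(labels, dtype=np.int32)
    next_label = 1
    for region in regionprops(labels):
        if params.min_area_px <= region.area <= params.max_area_px:
            out[labels == region.label] = next_label
            next_label += 1
    return out


def two_nearest_distances(centroids: np.ndarray, pixel_size: float = 1.0) -> np.ndarray:
    """Mean distance of each centroid to its two nearest neighbors (um).

    Requires at least 3 centroids (so every point has two neighbors).
    """
    centroids = np.asarray(centroids, dtype=float)
    if centroids.shape[0] < 3:
        raise ValueError("two_nearest_distances needs at least 3 centroids")
    d = cdist(centroids, centroids) * pixel_size
    np.fill_diagonal(d, np.inf)
    return np.sort(d, axis=1)[:, :2].mean(axis=1)


def nucleus_features(
    mask: np.ndarray,
    pixel_size: float,
    channel_images: dict[str, np.ndarray] | None = None,
    fov_id=0,
) -> pd.DataFrame:
    """Per-nucleus morphology and intensity features.

    Area is pixel count times ``pixel_size**2``; ``two_nearest_dist`` is the
    mean of the two smallest centroid-to-centroid distances (um), undefined
    (NaN) when the FOV holds fewer than 3 nuclei; mean channel intensities are
    computed over each label's pixels.
    """
    mask = np.asarray(mask)
    channel_images = channel_images or {}
    for name, img in channel_images.items():
        if img.shape != mask.shape:
            raise ValueError(f"channel {name!r} shape {img.shape} != mask shape {mask.shape}")
    regions = regionprops(mask)
    rows = []
    centroids = np.array([r.centroid for r in regions]) if regions else np.empty((0, 2))
    dists = two_nearest_distances(centroids, pixel_size) if len(regions) >= 3 else None
    for i, region in enumerate(regions):
        row = {
            "cell_id": int(region.label),
            "fov_id": fov_id,
            "nuclear_area": float(region.area) * pixel_size**2,
            "two_nearest_dist": float(dists[i]) if dists is not None else np.nan,
            "centroid_y_um": region.centroid[0] * pixel_size,
            "centroid_x_um": region.centroid[1] * pixel_size,
        }
        for name, img in channel_images.items():
            row[name] = float(np.asarray(img, dtype=float)[mask == region.label].mean())
        rows.append(row)
    df = pd.DataFrame(rows)
    if len(regions) < 3 and len(rows):
        logger.info("FOV %r has <3 nuclei; two_nearest_dist undefined", fov_id)
    return df


# ---------------------------------------------------------------------------
# Marker classification


def classify_marker(
    records: pd.DataFrame,
    method: str = "otsu_per_fov",
    threshold: float | None = None,
    intensity_column: str = "marker_intensity",
) -> pd.DataFrame:
    """Assign marker classes from marker intensities.

    ``fixed_threshold`` labels positive above the given threshold;
    ``otsu_per_fov`` computes an Otsu threshold per FOV.  FOVs whose
    intensities are constant (Otsu undefined) are left ``unassigned`` with a
    warning.  The threshold used per FOV is recorded in
    ``df.attrs['marker_thresholds']``.
    """
    if intensity_column not in records.columns:
        raise ValueError(f"records lack an {intensity_column!r} column")
    out = records.copy()
    out["marker_class"] = "unassigned"
    thresholds: dict = {}
    if method == "fixed_threshold":
        if threshold is None:
            raise ValueError("fixed_threshold method requires a threshold")
        out.loc[out[intensity_column] > threshold, "marker_class"] = "positive"
        out.loc[out[intensity_column] <= threshold, "marker_class"] = "negative"
        thresholds["all"] = threshold
    elif method == "otsu_per_fov":
        for fov, sub in out.groupby("fov_id"):
            values = sub[intensity_column].values.astype(float)
            if np.ptp(values) == 0 or len(values) < 2:
                logger.warning("FOV %r: constant marker intensities, cells left unassigned", fov)
                continue
            thr = threshold_otsu(values)
            thresholds[fov] = float(thr)
            out.loc[sub.index, "marker_class"] = np.where(values > thr, "positive", "negative")
    else:
        raise ValueError(f"unknown marker classification method {method!r}")
    out.attrs["marker_thresholds"] = thresholds
    return out


def marker_positive_fraction(records: pd.DataFrame, group: str = "fov_id") -> pd.Series:
    """Percentage of marker-positive cells among classified cells, per group.

    Groups with zero classified cells are absent from the output.
    """
    classified = records[records["marker_class"].isin(["positive", "negative"])]
    if classified.empty:
        return pd.Series(dtype=float, name="positive_pct")
    frac = classified.groupby(group)["marker_class"].apply(
        lambda s: 100.0 * (s == "positive").mean()
    )
    frac.name = "positive_pct"
    return frac


# ---------------------------------------------------------------------------
# Trajectory-to-cell assignment


def assign_trajectories_to_cells(
    trajectories: pd.DataFrame, mask: np.ndarray, pixel_size: float
) -> tuple[pd.DataFrame, int]:
    """Assign each trajectory to the nucleus label holding the majority of its
    localizations; ties and majority-background trajectories are discarded.

    Returns (table with ``cell_id`` overwritten, number of discarded
    trajectories).
    """
    mask = np.asarray(mask)
    h, w = mask.shape
    traj = trajectories.copy()
    col = np.clip((traj["x_um"].values / pixel_size).astype(int), 0, w - 1)
    row = np.clip((traj["y_um"].values / pixel_size).astype(int), 0, h - 1)
    traj["_label"] = mask[row, col]
    keep_frames = []
    n_discarded = 0
    for (fov, tid), sub in traj.groupby(["fov_id", "trajectory_id"], sort=False):
        counts = sub["_label"].value_counts()
        top = counts.index[0]
        if top == 0 or (len(counts) > 1 and counts.iloc[0] == counts.iloc[1]):
            n_discarded += 1
            continue
        sub = sub.copy()
        sub["cell_id"] = int(top)
        keep_frames.append(sub)
    if n_discarded:
        logger.info("%d trajectories discarded (background or ambiguous cell)", n_discarded)
    if not keep_frames:
        return trajectories.iloc[0:0].copy(), n_discarded
    out = pd.concat(keep_frames, ignore_index=True).drop(columns="_label")
    return out, n_discarded


def default_max_radius(d_max: float, dt: float) -> float:
    """Linking radius ``2.45 * sqrt(4 * D_max * dt)`` um.

    The Rayleigh 95th percentile of a lag-1 jump of the fastest state is
    ``2.448 * sqrt(2 * D_max * dt)``; the default uses the conventional
    ``sqrt(4 D dt)`` scale instead, which captures well over 95% of those
    jumps while staying small against typical inter-molecule distances at
    sparse labeling densities.
    """
    return float(2.45 * np.sqrt(4.0 * d_max * dt))
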