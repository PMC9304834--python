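"""Deterministic streamline tracking on per-voxel orientation peaks.

Direction lookup is nearest-voxel peak selection with sign disambiguation
(among a voxel's peaks, take the one minimizing the angle to the incoming
direction, flipped to the hemisphere of travel); no direction interpolation.
Propagation is bidirectional from each seed with fixed step length, halting on
mask exit, missing peak, angular threshold, or maximum length.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grid import VoxelGrid
from .parcel_select import ParcellationVolume

__all__ = [
    "OrientationField", "TrackingParams", "Streamline", "SubjectConnectome",
    "track_one", "whole_brain_track", "two_roi_filter", "subject_connectome",
    "split_region_name", "streamlines_to_frame",
]


def streamlines_to_frame(streamlines: list["Streamline"]) -> "pd.DataFrame":
    """TRK-like long table: (streamline id, point index, x, y, z)."""
    rows = []
    for i, sl in enumerate(streamlines):
        for j, (x, y, z) in enumerate(sl.points):
            rows.append((i, j, x, y, z))
    return pd.DataFrame(rows, columns=["streamline", "point", "x", "y", "z"])


@dataclass
class OrientationField:
    grid: VoxelGrid
    peaks: np.ndarray  # (X, Y, Z, K, 3); zero vectors mark absent peaks

    def __post_init__(self):
        self.peaks = np.asarray(self.peaks, dtype=np.float32)
        if self.peaks.ndim != 5 or self.peaks.shape[:3] != self.grid.shape or self.peaks.shape[4] != 3:
            raise ValueError("peaks must have shape (X, Y, Z, K, 3) matching the grid")
        norms = np.linalg.norm(self.peaks, axis=-1)
        present = norms > 0.5
        if present.any() and not np.allclose(norms[present], 1.0, atol=1e-5):
            raise ValueError("peak directions must be unit vectors")
        out = present & ~self.grid.mask[..., None]
        if out.any():
            raise ValueError("peaks present outside the mask")

    @property
    def mask(self) -> np.ndarray:
        return self.grid.mask


@dataclass
class TrackingParams:
    angular_threshold_deg: float = 45.0
    step_mm: float = 1.5
    max_len_mm: float = 800.0
    min_len_mm: float = 1.0
    n_seeds: int = 1_000_000
    rng_seed: int = 0

    def __post_init__(self):
        if not 0 < self.angular_threshold_deg < 90:
            raise ValueError("angular threshold must be in (0, 90) degrees")
        if self.step_mm <= 0:
            raise ValueError("step_mm must be positive")
        if not self.min_len_mm < self.max_len_mm:
            raise ValueError("min_len_mm must be below max_len_mm")
        if self.n_seeds < 1:
            raise ValueError("n_seeds must be >= 1")


@dataclass
class Streamline:
    points: np.ndarray  # (n, 3) mm

    @property
    def length(self) -> float:
        return float(np.linalg.norm(np.diff(self.points, axis=0), axis=1).sum())


@dataclass
class SubjectConnectome:
    subject_id: str
    counts: dict = field(default_factory=dict)  # (regionA, regionB, hemi) -> int

    def count(self, a: str, b: str, hemi: str) -> int:
        a, b = sorted((a, b))
        return int(self.counts.get((a, b, hemi), 0))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([
            {"subject": self.subject_id, "region_a": a, "region_b": b,
             "hemisphere": h, "count": c}
            for (a, b, h), c in sorted(self.counts.items())
        ])


def _best_peak(peaks_v: np.ndarray, direction: np.ndarray,
               cos_thresh: float) -> np.ndarray | None:
    """Sign-disambiguated peak closest in angle to ``direction``, or None."""
    norms = np.linalg.norm(peaks_v, axis=-1)
    ok = norms > 0.5
    if not ok.any():
        return None
    cand = peaks_v[ok]
    dots = cand @ direction
    i = int(np.argmax(np.abs(dots)))
    d = cand[i] if dots[i] >= 0 else -cand[i]
    if abs(dots[i]) < cos_thresh:
        return None  # direction change above the angular threshold
    return d


def _propagate(field: OrientationField, start: np.ndarray, direction: np.ndarray,
               params: TrackingParams, max_steps: int) -> list[np.ndarray]:
    """Forward half-track: points after ``start`` (may be empty)."""
    grid = field.grid
    cos_thresh = float(np.cos(np.deg2rad(params.angular_threshold_deg)))
    pts: list[np.ndarray] = []
    p = np.asarray(start, dtype=float)
    d = np.asarray(direction, dtype=float)
    for _ in range(max_steps):
        p_new = p + params.step_mm * d
        v = grid.nearest_voxel(p_new)
        if v is None or not grid.mask[v]:
            break
        pts.append(p_new)
        d_new = _best_peak(field.peaks[v], d, cos_thresh)
        if d_new is None:
            break
        p, d = p_new, d_new
    return pts


def track_one(field: OrientationField, seed_point, params: TrackingParams) -> Streamline | None:
    """Bidirectional deterministic track from one seed; None when discarded."""
    grid = field.grid
    seed = np.asarray(seed_point, dtype=float)
    v = grid.nearest_voxel(seed)
    if v is None or not grid.mask[v]:
        return None
    norms = np.linalg.norm(field.peaks[v], axis=-1)
    ok = np.flatnonzero(norms > 0.5)
    if ok.size == 0:
        return None
    d0 = np.asarray(field.peaks[v][ok[0]], dtype=float)

    max_steps = int(np.floor(params.max_len_mm / params.step_mm))
    fwd = _propagate(field, seed, d0, params, max_steps)
    bwd = _propagate(field, seed, -d0, params, max_steps - len(fwd))
    points = np.asarray(bwd[::-1] + [seed] + fwd)
    length = (len(points) - 1) * params.step_mm
    if length < params.min_len_mm:
        return None
    return Streamline(points=points)


def whole_brain_track(field: OrientationField, params: TrackingParams) -> list[Streamline]:
    """One track attempt per uniformly drawn in-mask seed; deterministic given seed."""
    if params.n_seeds < 1:
        raise ValueError("n_seeds must be >= 1")
    grid = field.grid
    if params.step_mm > 2.0 * float(grid.spacing.min()):
        raise ValueError("step_mm too large for the grid spacing")
    mask_idx = np.argwhere(grid.mask)
    if len(mask_idx) == 0:
        raise ValueError("empty mask")
    rng = np.random.default_rng(params.rng_seed)
    picks = rng.integers(0, len(mask_idx), size=params.n_seeds)
    offsets = rng.uniform(-0.5, 0.5, size=(params.n_seeds, 3))
    seeds = grid.voxel_to_mm(mask_idx[picks] + offsets)
    out = []
    for s in seeds:
        sl = track_one(field, s, params)
        if sl is not None:
            out.append(sl)
    return out


def _endpoint_voxels(sl: Streamline, grid: VoxelGrid):
    return grid.nearest_voxel(sl.points[0]), grid.nearest_voxel(sl.points[-1])


def two_roi_filter(streamlines: list[Streamline], roi_a: np.ndarray, roi_b: np.ndarray,
                   grid: VoxelGrid, exclusions: list[np.ndarray] | None = None) -> int:
    """Count streamlines with one endpoint in each ROI.

    Streamlines intersecting any exclusion ROI are dropped first.
    """
    roi_a = np.asarray(roi_a, dtype=bool)
    roi_b = np.asarray(roi_b, dtype=bool)
    if (roi_a & roi_b).any():
        raise ValueError("roi_a and roi_b overlap")
    exclusions = exclusions or []
    shape = np.asarray(grid.shape)
    n = 0
    for sl in streamlines:
        if exclusions:
            vox = np.rint(grid.mm_to_voxel(sl.points)).astype(int)
            ok = np.all((vox >= 0) & (vox < shape), axis=1)
            vox = vox[ok]
            if any(exc[tuple(vox.T)].any() for exc in exclusions):
                continue
        va, vb = _endpoint_voxels(sl, grid)
        if va is None or vb is None:
            continue
        if (roi_a[va] and roi_b[vb]) or (roi_a[vb] and roi_b[va]):
            n += 1
    return n


def split_region_name(name: str) -> tuple[str, str]:
    """'L_AVI' -> ('L', 'AVI'); names without a hemisphere prefix get hemi ''. """
    if name[:2] in ("L_", "R_"):
        return name[0], name[2:]
    return "", name


def subject_connectome(field: OrientationField, parc: ParcellationVolume,
                       params: TrackingParams, subject_id: str = "subject") -> SubjectConnectome:
    """Whole-brain pass, then per-pair endpoint counting per hemisphere.

    Equivalent to applying :func:`two_roi_filter` (without exclusions) to every
    unordered hemispheric region pair of the parcellation.
    """
    regions = parc.regions
    if len(regions) < 2:
        raise ValueError("need at least 2 regions")
    if parc.grid.shape != field.grid.shape or not np.allclose(parc.grid.affine, field.grid.affine):
        raise ValueError("parcellation and field grids differ")
    streamlines = whole_brain_track(field, params)

    labels = parc.labels
    counts: dict[tuple[str, str, str], int] = {}
    for sl in streamlines:
        va, vb = _endpoint_voxels(sl, field.grid)
        if va is None or vb is None:
            continue
        la, lb = int(labels[va]), int(labels[vb])
        if la == 0 or lb == 0 or la == lb:
            continue
        ha, a = split_region_name(parc.name_map[la])
        hb, b = split_region_name(parc.name_map[lb])
        if ha != hb:
            continue  # interhemispheric endpoints are outside the per-hemisphere model
        a, b = sorted((a, b))
        key = (a, b, ha)
        counts[key] = counts.get(key, 0) + 1
    return SubjectConnectome(subject_id=subject_id, counts=counts)
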