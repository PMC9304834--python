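"""Ground-truth generators: foci tables, blob parcellations, bundle cohorts.

Everything the pipeline consumes can be generated here with known ground
truth, so recovery can be tested end-to-end without any external imaging data.
Bundle count asymmetry is implemented by scaling the tube cross-section
(radius * sqrt(scale)), so expected streamline-count ratios equal the
count_scale ratio under uniform whole-brain seeding.
"""
from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .foci_io import FociTable, Focus, StudyRecord, packaged_foci_path, parse_foci_table
from .grid import VoxelGrid
from .parcel_select import ParcellationVolume
from .tractography import OrientationField

__all__ = [
    "FociSpec", "BundleSpec", "gen_foci", "gen_parcellation", "gen_cohort",
    "fixture_tables", "load_edge_fixture", "synthetic_grid",
]

# sha256 of the packaged fixture files; fixture_tables refuses to serve a
# silently edited transcription
_TABLE1_SHA256 = "22e43ab5d28b6f8ac96553549ad18aaef69253d4cb21bee1d38f59221e02f860"
_TABLE2_SHA256 = "28b7884a42f9b1e4469822131c03e9a48e89e9fa0ed39a719225e0a6862fc756"


def synthetic_grid(spacing_mm: float = 1.0,
                   shape: tuple[int, int, int] = (80, 96, 80)) -> VoxelGrid:
    """Small centered grid used by the synthetic generators (1 mm default)."""
    affine = np.diag([spacing_mm] * 3 + [1.0])
    affine[:3, 3] = -np.asarray(shape, dtype=float) * spacing_mm / 2.0
    return VoxelGrid(shape=shape, affine=affine, mask=np.ones(shape, bool))


# ---------------------------------------------------------------------------
# Foci
# ---------------------------------------------------------------------------

@dataclass
class FociSpec:
    loci: list  # list of mm coordinates
    n_studies: int = 10
    subjects_range: tuple[int, int] = (14, 255)
    jitter_sigma: float = 4.0
    foci_per_study_per_locus: int = 1
    background_foci: int = 0
    seed: int = 0

    def __post_init__(self):
        if self.jitter_sigma < 0:
            raise ValueError("jitter_sigma must be >= 0")
        if min(self.n_studies, self.foci_per_study_per_locus, self.background_foci) < 0:
            raise ValueError("counts must be >= 0")


def gen_foci(spec: FociSpec, grid: VoxelGrid | None = None) -> FociTable:
    """Clustered synthetic foci table; deterministic given spec.seed."""
    rng = np.random.default_rng(spec.seed)
    if spec.background_foci > 0 and grid is None:
        raise ValueError("background foci require a grid")
    centers = grid.voxel_centers_mm() if grid is not None else None
    studies = []
    for i in range(spec.n_studies):
        n = int(rng.integers(spec.subjects_range[0], spec.subjects_range[1] + 1))
        foci = []
        for locus in spec.loci:
            for _ in range(spec.foci_per_study_per_locus):
                p = np.asarray(locus, dtype=float) + rng.normal(0.0, spec.jitter_sigma, 3)
                foci.append(Focus(x=p[0], y=p[1], z=p[2], space="MNI"))
        for _ in range(spec.background_foci):
            p = centers[rng.integers(0, len(centers))]
            foci.append(Focus(x=p[0], y=p[1], z=p[2], space="MNI"))
        studies.append(StudyRecord(study_id=f"synth_{i:03d}", task="synthetic",
                                   n_subjects=n, foci=tuple(foci)))
    return FociTable(studies)


# ---------------------------------------------------------------------------
# Parcellation
# ---------------------------------------------------------------------------

def gen_parcellation(grid: VoxelGrid, parcel_specs: list[tuple],
                     mirror: bool = True) -> ParcellationVolume:
    """Spherical parcels, mirrored across x = 0 into L/R hemispheres.

    ``parcel_specs`` rows: (name, cluster, center_mm, radius_mm) with x >= 0
    (the right-hemisphere position). Overlap after voxelization is an error.
    """
    labels = np.zeros(grid.shape, dtype=np.int32)
    name_map: dict[int, str] = {}
    cluster_map: dict[str, str] = {}
    idx = np.indices(grid.shape).reshape(3, -1).T
    centers = grid.voxel_to_mm(idx.astype(float))
    owner: dict[int, str] = {}

    def place(label: int, name: str, center: np.ndarray, radius: float):
        d2 = ((centers - center) ** 2).sum(axis=1)
        sel = np.flatnonzero(d2 <= radius * radius)
        if sel.size == 0:
            raise ValueError(f"parcel {name!r} voxelizes to nothing")
        taken = [owner[s] for s in sel if s in owner]
        if taken:
            raise ValueError(f"parcels overlap after voxelization: {name!r} and {taken[0]!r}")
        for s in sel:
            owner[s] = name
        labels.ravel()[sel] = label
        name_map[label] = name

    label = 0
    for name, cluster, center, radius in parcel_specs:
        center = np.asarray(center, dtype=float)
        cluster_map[name] = cluster
        sides = [("R", center)]
        if mirror:
            sides.append(("L", center * np.array([-1.0, 1.0, 1.0])))
        for hemi, c in sides:
            label += 1
            place(label, f"{hemi}_{name}", c, float(radius))
    return ParcellationVolume(grid=grid, labels=labels, name_map=name_map,
                              cluster_map=cluster_map)


# ---------------------------------------------------------------------------
# Bundles / cohort
# ---------------------------------------------------------------------------

@dataclass
class BundleSpec:
    kind: str  # straight | arc | u_shape
    region_a: str
    region_b: str
    tube_radius_mm: float = 2.0
    arc_height_mm: float | None = None  # arc bulge; default chord/4 (u_shape: chord/2)
    presence_prob: float = 1.0
    count_scale: tuple[int, int] = (1, 1)  # (left, right) parallel tube copies

    def __post_init__(self):
        if self.kind not in ("straight", "arc", "u_shape"):
            raise ValueError(f"unknown bundle kind {self.kind!r}")
        if not 0.0 <= self.presence_prob <= 1.0:
            raise ValueError("presence_prob must be in [0,1]")
        if self.tube_radius_mm <= 0:
            raise ValueError("tube radius must be positive")
        if (min(self.count_scale) < 1
                or any(int(s) != s for s in self.count_scale)):
            raise ValueError("count_scale entries must be positive integers")


def _centerline(kind: str, pa: np.ndarray, pb: np.ndarray,
                arc_height: float | None, ds: float = 0.25) -> tuple[np.ndarray, np.ndarray]:
    """Densely sampled centerline from pa to pb plus its binormal unit vector.

    Parallel copies of a bundle are displaced along the binormal, which leaves
    the curve geometry (and hence streamline retention) unchanged.
    """
    chord = pb - pa
    c = np.linalg.norm(chord)
    if c < 1e-9:
        raise ValueError("bundle endpoints coincide")
    u = chord / c
    up = np.array([0.0, 0.0, 1.0])
    n_vec = up - (up @ u) * u
    if np.linalg.norm(n_vec) < 1e-6:
        n_vec = np.array([0.0, 1.0, 0.0]) - (np.array([0.0, 1.0, 0.0]) @ u) * u
    n_vec /= np.linalg.norm(n_vec)
    axis = np.cross(u, n_vec)
    axis /= np.linalg.norm(axis)
    if kind == "straight":
        n = max(int(np.ceil(c / ds)), 2)
        t = np.linspace(0.0, 1.0, n)
        return pa[None, :] + t[:, None] * chord[None, :], axis
    h = arc_height if arc_height is not None else (c / 2.0 if kind == "u_shape" else c / 4.0)
    # circle through pa, pb and the apex at midpoint + h * n_vec
    radius = h / 2.0 + c * c / (8.0 * h)
    mid = (pa + pb) / 2.0
    center = mid + (h - radius) * n_vec
    theta = 2.0 * np.arcsin(min(1.0, c / (2.0 * radius)))
    if h > radius:  # major arc (> 180 degrees)
        theta = 2.0 * np.pi - theta
    va = pa - center
    n_s = max(int(np.ceil(radius * theta / ds)), 2)
    angles = np.linspace(0.0, theta, n_s)
    sign = 1.0 if np.allclose(_rotate(va, axis, theta) + center, pb, atol=1e-6) else -1.0
    return np.array([center + _rotate(va, axis, sign * a) for a in angles]), axis


def _rotate(v: np.ndarray, axis: np.ndarray, angle: float) -> np.ndarray:
    c, s = np.cos(angle), np.sin(angle)
    return v * c + np.cross(axis, v) * s + axis * (axis @ v) * (1.0 - c)


def _tube_voxels(grid: VoxelGrid, line: np.ndarray, radius: float):
    """(voxel indices inside the tube, unit tangent per voxel, nearest sample)."""
    v1 = grid.mm_to_voxel(line.min(axis=0) - radius)
    v2 = grid.mm_to_voxel(line.max(axis=0) + radius)
    lo = np.floor(np.minimum(v1, v2)).astype(int)
    hi = np.ceil(np.maximum(v1, v2)).astype(int)
    if np.any(lo < 0) or np.any(hi >= np.asarray(grid.shape)):
        raise ValueError("bundle tube exits the grid")
    ranges = [np.arange(a, b + 1) for a, b in zip(lo, hi)]
    box = np.stack(np.meshgrid(*ranges, indexing="ij"), axis=-1).reshape(-1, 3)
    mm = grid.voxel_to_mm(box.astype(float))
    tree = cKDTree(line)
    dist, nearest = tree.query(mm)
    sel = dist <= radius
    tangents = np.gradient(line, axis=0)
    tangents /= np.linalg.norm(tangents, axis=1, keepdims=True)
    return box[sel], tangents[nearest[sel]], nearest[sel]


def _arclength_window(line: np.ndarray, center_a: np.ndarray, radius_a: float,
                      center_b: np.ndarray, radius_b: float, margin: float):
    """Arclength interval of the centerline clear of both endpoint-parcel cores.

    The tube (and all its parallel copies) is cut at the same arclength on
    every copy, so per-copy voxel counts stay equal regardless of where each
    copy grazes the spherical parcels. ``margin`` must leave the cut
    cross-section of the widest copy fully inside its parcel.
    """
    if radius_a <= margin or radius_b <= margin:
        raise ValueError("endpoint parcel too small for the bundle tube/offsets")
    seg = np.linalg.norm(np.diff(line, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    da = np.linalg.norm(line - center_a, axis=1)
    db = np.linalg.norm(line - center_b, axis=1)
    out_a = np.flatnonzero(da >= radius_a - margin)
    out_b = np.flatnonzero(db >= radius_b - margin)
    if out_a.size == 0 or out_b.size == 0:
        raise ValueError("bundle centerline never leaves its endpoint parcels")
    return s[out_a[0]], s[out_b[-1]], s


def gen_cohort(bundles: list[BundleSpec], parc: ParcellationVolume, n_subjects: int,
               seed: int = 0, max_peaks: int = 3) -> tuple[list[OrientationField], pd.DataFrame]:
    """Per-subject orientation fields with planted bundles + ground-truth table.

    Each bundle runs between the hemispheric mirrors of its endpoint parcels;
    a single Bernoulli(presence_prob) draw per subject controls both
    hemispheres. count_scale plants that many parallel tube copies displaced
    along the binormal; every copy is cut at the same centerline arclength
    just inside the endpoint parcels, so copies have equal voxel counts and
    expected streamline-count ratios equal the scale ratio.
    """
    grid = parc.grid
    region_centers: dict[str, np.ndarray] = {}
    region_radius: dict[str, float] = {}
    for label, name in parc.name_map.items():
        vox = np.argwhere(parc.labels == label)
        region_centers[name] = parc.grid.voxel_to_mm(vox.astype(float)).mean(axis=0)
        # effective sphere radius from the voxelized volume
        region_radius[name] = float((3.0 * len(vox) * grid.voxel_volume / (4.0 * np.pi)) ** (1 / 3))

    # precompute tube voxels/tangents once per (bundle, hemisphere)
    rasters: dict[tuple[int, str], tuple[np.ndarray, np.ndarray]] = {}
    for bi, b in enumerate(bundles):
        for hemi, scale in (("L", b.count_scale[0]), ("R", b.count_scale[1])):
            ka, kb = f"{hemi}_{b.region_a}", f"{hemi}_{b.region_b}"
            if ka not in region_centers or kb not in region_centers:
                raise ValueError(f"bundle endpoint {b.region_a!r}/{b.region_b!r} not in parcellation")
            line, binormal = _centerline(b.kind, region_centers[ka], region_centers[kb],
                                         b.arc_height_mm)
            spacing = 2.0 * b.tube_radius_mm + 1.0
            max_scale = max(b.count_scale)
            max_offset = (max_scale - 1) / 2.0 * spacing
            margin = max_offset + b.tube_radius_mm + 1.0
            s_lo, s_hi, _ = _arclength_window(line, region_centers[ka], region_radius[ka],
                                              region_centers[kb], region_radius[kb], margin)
            all_vox, all_tang = [], []
            for ci in range(int(scale)):
                offset = (ci - (scale - 1) / 2.0) * spacing * binormal
                vox, tang, nearest = _tube_voxels(grid, line + offset, b.tube_radius_mm)
                seg = np.linalg.norm(np.diff(line, axis=0), axis=1)
                s = np.concatenate([[0.0], np.cumsum(seg)])
                keep = (s[nearest] >= s_lo) & (s[nearest] <= s_hi)
                all_vox.append(vox[keep])
                all_tang.append(tang[keep])
            rasters[(bi, hemi)] = (np.concatenate(all_vox), np.concatenate(all_tang))

    # common mask: parcels + every tube (presence only removes peaks, not mask)
    mask = parc.labels > 0
    for vox, _ in rasters.values():
        mask[tuple(vox.T)] = True
    field_grid = VoxelGrid(shape=grid.shape, affine=grid.affine.copy(), mask=mask)

    rng = np.random.default_rng(seed)
    fields: list[OrientationField] = []
    truth_rows = []
    for si in range(n_subjects):
        sid = f"subj{si:02d}"
        peaks = np.zeros(grid.shape + (max_peaks, 3), dtype=np.float32)
        filled = np.zeros(grid.shape, dtype=np.int8)
        for bi, b in enumerate(bundles):
            present = bool(rng.random() < b.presence_prob)
            for hemi, scale in (("L", b.count_scale[0]), ("R", b.count_scale[1])):
                if present:
                    vox, tang = rasters[(bi, hemi)]
                    for (x, y, z), t in zip(vox, tang):
                        k = filled[x, y, z]
                        if k < max_peaks:
                            peaks[x, y, z, k] = t
                            filled[x, y, z] = k + 1
                a, b_name = sorted((b.region_a, b.region_b))
                truth_rows.append({"subject": sid, "region_a": a, "region_b": b_name,
                                   "hemisphere": hemi, "present": present,
                                   "scale": scale, "kind": b.kind})
        fields.append(OrientationField(grid=field_grid, peaks=peaks))
    return fields, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# Packaged fixtures
# ---------------------------------------------------------------------------

def _sha256(path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def load_edge_fixture() -> pd.DataFrame:
    path = resources.files("salnet.data").joinpath("table2_edges.csv")
    return pd.read_csv(path)


def fixture_tables(verify_checksum: bool = True) -> tuple[FociTable, pd.DataFrame]:
    """The packaged study/foci transcription and edge-statistics table."""
    foci_path = packaged_foci_path()
    edges_path = resources.files("salnet.data").joinpath("table2_edges.csv")
    if verify_checksum:
        for path, want in ((foci_path, _TABLE1_SHA256), (edges_path, _TABLE2_SHA256)):
            got = _sha256(path)
            if got != want:
                raise ValueError(f"fixture checksum mismatch for {path.name}: {got}")
    return parse_foci_table(str(foci_path)), pd.read_csv(edges_path)
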