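"""Activation-likelihood-estimation maps and permutation cluster inference.

Each study contributes a modeled-activation (MA) map: a mass-normalized 3-D
Gaussian per focus, combined by voxelwise MAX over the study's foci. The ALE
statistic is the complement-product union over studies,
``ALE(v) = 1 - prod_i (1 - MA_i(v))``.

Significance is Monte-Carlo: every study's foci are relocated uniformly at
random within the mask, the ALE recomputed per permutation, voxelwise p-values
taken with the plus-one estimator, and cluster extents compared against the
permutation distribution of the maximum cluster size. This replaces the
analytic histogram null of the reference implementation with an explicit,
enumerable permutation null.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats

from .foci_io import FociTable, StudyRecord
from .grid import VoxelGrid

logger = logging.getLogger(__name__)

__all__ = [
    "ALEParams", "MAMap", "Cluster", "ALEResult", "ALENull",
    "fwhm_for_sample_size", "ma_map", "ale_union", "observed_ale",
    "voxel_null", "mc_pvalues", "find_clusters", "cluster_inference",
]

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))
# Kernel truncation radius in sigmas. The 3-D Gaussian mass beyond 7.5 sigma
# is < 1e-11, asserted at kernel build time; 7.5 sigma ~ 3.2 FWHM.
_TRUNC_SIGMA = 7.5

# Empirical spatial-uncertainty model of coordinate-based meta-analysis
# (Eickhoff et al. 2009): Euclidean displacement of a focus has a
# between-subject component of 11.6 mm (shrinking with sqrt(n)) and a
# between-template component of 5.7 mm. Per-axis sigma = ED / sqrt(8/pi).
_ED_BETWEEN_SUBJECT_MM = 11.6
_ED_BETWEEN_TEMPLATE_MM = 5.7
_ED_TO_SIGMA = 1.0 / np.sqrt(8.0 / np.pi)


def fwhm_for_sample_size(n_subjects: int) -> float:
    """Per-study Gaussian FWHM (mm) from the subject count."""
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    var = (_ED_BETWEEN_SUBJECT_MM ** 2 / n_subjects + _ED_BETWEEN_TEMPLATE_MM ** 2) * _ED_TO_SIGMA ** 2
    return float(np.sqrt(var) / _FWHM_TO_SIGMA)


@dataclass
class ALEParams:
    cluster_alpha: float = 0.05
    voxel_p_threshold: float = 0.001
    n_perm: int = 1000
    kernel_fwhm: float | None = None  # None -> per-study from n_subjects
    rng_seed: int = 0
    connectivity: int = 26

    def __post_init__(self):
        if not 0 < self.cluster_alpha < 1:
            raise ValueError("cluster_alpha must be in (0,1)")
        if not 0 < self.voxel_p_threshold < 1:
            raise ValueError("voxel_p_threshold must be in (0,1)")
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        if self.kernel_fwhm is not None and self.kernel_fwhm <= 0:
            raise ValueError("kernel_fwhm must be positive")
        if self.connectivity not in (6, 18, 26):
            raise ValueError("connectivity must be 6, 18 or 26")

    def to_dict(self) -> dict:
        return {
            "cluster_alpha": self.cluster_alpha,
            "voxel_p_threshold": self.voxel_p_threshold,
            "n_perm": self.n_perm, "kernel_fwhm": self.kernel_fwhm,
            "rng_seed": self.rng_seed, "connectivity": self.connectivity,
        }


@dataclass
class MAMap:
    grid: VoxelGrid
    values: np.ndarray
    study_id: str


@dataclass
class Cluster:
    indices: np.ndarray  # (n, 3) int voxel indices
    size: int
    peak_mm: np.ndarray
    p: float


@dataclass
class ALEResult:
    grid: VoxelGrid
    ale: np.ndarray
    voxel_p: np.ndarray
    clusters: list[Cluster]
    params: dict = field(default_factory=dict)

    @property
    def cluster_peaks_mm(self) -> np.ndarray:
        return np.array([c.peak_mm for c in self.clusters]).reshape(-1, 3)


@dataclass
class ALENull:
    voxel_p: np.ndarray        # 3-D uncorrected p (1.0 outside mask)
    observed: np.ndarray       # 3-D observed ALE
    perm_values: np.ndarray    # (n_perm, n_mask_voxels) float32 permuted ALE


# ---------------------------------------------------------------------------
# Kernel stamping
# ---------------------------------------------------------------------------

_kernel_cache: dict[tuple, tuple[np.ndarray, int]] = {}


def _centered_kernel(fwhm: float, grid: VoxelGrid) -> tuple[np.ndarray, int]:
    """Voxel-center-aligned normalized kernel for a diagonal-affine grid."""
    key = (round(fwhm, 9), tuple(np.round(grid.spacing, 9)))
    hit = _kernel_cache.get(key)
    if hit is not None:
        return hit
    sigma = fwhm * _FWHM_TO_SIGMA
    assert stats.chi(3).sf(_TRUNC_SIGMA) < 1e-10  # truncated mass bound
    r = int(np.ceil(_TRUNC_SIGMA * sigma / grid.spacing.min()))
    ax = [np.arange(-r, r + 1) * s for s in grid.spacing]
    d2 = (ax[0][:, None, None] ** 2 + ax[1][None, :, None] ** 2
          + ax[2][None, None, :] ** 2)
    k = np.exp(-d2 / (2.0 * sigma * sigma))
    k /= k.sum()
    _kernel_cache[key] = (k, r)
    return k, r


def _is_diagonal(affine: np.ndarray) -> bool:
    lin = affine[:3, :3]
    return np.allclose(lin, np.diag(np.diag(lin)))


def _stamp_max(values: np.ndarray, grid: VoxelGrid, center_mm, fwhm: float) -> bool:
    """Max-combine one focus' normalized Gaussian into ``values``.

    Returns False when the contribution lies entirely outside the array.
    """
    cv = grid.mm_to_voxel(np.asarray(center_mm, dtype=float))
    base = np.rint(cv).astype(int)
    frac = cv - base
    shape = np.asarray(grid.shape)

    if np.all(np.abs(frac) < 1e-9) and _is_diagonal(grid.affine):
        k, r = _centered_kernel(fwhm, grid)
        lo = base - r
        hi = base + r + 1
        klo = np.maximum(0, -lo)
        khi = (2 * r + 1) - np.maximum(0, hi - shape)
        lo_c = np.maximum(lo, 0)
        hi_c = np.minimum(hi, shape)
        if np.any(lo_c >= hi_c):
            return False
        dst = tuple(slice(a, b) for a, b in zip(lo_c, hi_c))
        src = tuple(slice(a, b) for a, b in zip(klo, khi))
        np.maximum(values[dst], k[src], out=values[dst])
        return True

    sigma = fwhm * _FWHM_TO_SIGMA
    trunc = _TRUNC_SIGMA * sigma
    r = np.ceil(trunc / grid.spacing + np.abs(frac)).astype(int)
    ax = [np.arange(b - ri, b + ri + 1) for b, ri in zip(base, r)]
    dv = [a - c for a, c in zip(ax, cv)]
    lin = grid.affine[:3, :3]
    d2 = np.zeros((len(ax[0]), len(ax[1]), len(ax[2])))
    for i in range(3):
        mm = (lin[i, 0] * dv[0][:, None, None] + lin[i, 1] * dv[1][None, :, None]
              + lin[i, 2] * dv[2][None, None, :])
        d2 += mm * mm
    k = np.exp(-d2 / (2.0 * sigma * sigma))
    k /= k.sum()  # mass over the full (unclipped) window
    sel = [(a >= 0) & (a < s) for a, s in zip(ax, shape)]
    if not all(s.any() for s in sel):
        return False
    dst = np.ix_(ax[0][sel[0]], ax[1][sel[1]], ax[2][sel[2]])
    values[dst] = np.maximum(values[dst], k[np.ix_(sel[0], sel[1], sel[2])])
    return True


# ---------------------------------------------------------------------------
# MA / ALE maps
# ---------------------------------------------------------------------------

def ma_map(study: StudyRecord, grid: VoxelGrid, kernel_fwhm: float | None = None) -> MAMap:
    """Modeled-activation map of one study (voxelwise MAX over foci kernels)."""
    if study.space != "MNI":
        raise ValueError(f"study {study.study_id!r} must be in MNI space")
    fwhm = kernel_fwhm if kernel_fwhm is not None else fwhm_for_sample_size(study.n_subjects)
    if fwhm <= 0:
        raise ValueError("kernel_fwhm must be positive")
    values = np.zeros(grid.shape, dtype=float)
    for f in study.foci:
        if not _stamp_max(values, grid, f.xyz, fwhm):
            logger.warning("focus %s of study %r outside grid; contribution truncated",
                           tuple(f.xyz), study.study_id)
    values[~grid.mask] = 0.0
    np.clip(values, 0.0, 1.0, out=values)
    return MAMap(grid=grid, values=values, study_id=study.study_id)


def ale_union(maps: list[MAMap] | list[np.ndarray]) -> np.ndarray:
    """ALE(v) = 1 - prod_i (1 - MA_i(v))."""
    if not maps:
        raise ValueError("empty MA map list")
    arrays = [m.values if isinstance(m, MAMap) else np.asarray(m) for m in maps]
    shape = arrays[0].shape
    if any(a.shape != shape for a in arrays):
        raise ValueError("MA maps must share one grid")
    out = np.ones(shape, dtype=float)
    for a in arrays:
        out *= 1.0 - a
    return 1.0 - out


def observed_ale(table: FociTable, grid: VoxelGrid,
                 kernel_fwhm: float | None = None) -> np.ndarray:
    return ale_union([ma_map(s, grid, kernel_fwhm) for s in table.studies])


# ---------------------------------------------------------------------------
# Permutation null
# ---------------------------------------------------------------------------

def _permuted_ale(table: FociTable, grid: VoxelGrid, kernel_fwhm: float | None,
                  mask_centers: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One relocation permutation: every focus uniform over mask voxel centers."""
    out = np.ones(grid.shape, dtype=float)
    for s in table.studies:
        fwhm = kernel_fwhm if kernel_fwhm is not None else fwhm_for_sample_size(s.n_subjects)
        ma = np.zeros(grid.shape, dtype=float)
        picks = rng.integers(0, len(mask_centers), size=len(s.foci))
        for j in picks:
            _stamp_max(ma, grid, mask_centers[j], fwhm)
        ma[~grid.mask] = 0.0
        out *= 1.0 - ma
    return 1.0 - out


def voxel_null(table: FociTable, grid: VoxelGrid, kernel_fwhm: float | None,
               n_perm: int, seed: int = 0) -> ALENull:
    """Voxelwise Monte-Carlo p-values for the observed ALE map.

    p(v) = (1 + #{perm ALE(v) >= observed(v)}) / (n_perm + 1).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    mask_flat = np.flatnonzero(grid.mask.ravel())
    mask_centers = grid.voxel_centers_mm()
    obs = observed_ale(table.to_mni(), grid, kernel_fwhm)
    obs_m = obs.ravel()[mask_flat]

    perms = np.empty((n_perm, mask_flat.size), dtype=np.float32)
    for k in range(n_perm):
        perms[k] = _permuted_ale(table, grid, kernel_fwhm, mask_centers, rng).ravel()[mask_flat]

    p = np.ones(grid.shape, dtype=float)
    p.ravel()[mask_flat] = mc_pvalues(perms, obs_m)
    return ALENull(voxel_p=p, observed=obs, perm_values=perms)


def mc_pvalues(perm_values: np.ndarray, observed: np.ndarray) -> np.ndarray:
    """Plus-one Monte-Carlo p per column: (1 + #{perm >= obs}) / (n_perm + 1)."""
    count_ge = (perm_values >= np.asarray(observed, dtype=perm_values.dtype)).sum(axis=0)
    return (1.0 + count_ge) / (perm_values.shape[0] + 1.0)


def find_clusters(binary: np.ndarray, connectivity: int = 26) -> list[np.ndarray]:
    """Maximal connected components of a boolean volume as (n, 3) index arrays."""
    binary = np.asarray(binary, dtype=bool)
    order = {6: 1, 18: 2, 26: 3}[connectivity]
    structure = ndimage.generate_binary_structure(3, order)
    labels, n = ndimage.label(binary, structure=structure)
    return [np.argwhere(labels == i) for i in range(1, n + 1)]


def cluster_inference(table: FociTable, grid: VoxelGrid,
                      params: ALEParams | None = None) -> ALEResult:
    """Full ALE with permutation cluster-level inference.

    Clusters are formed from voxels with uncorrected p below the
    cluster-forming threshold; a cluster is significant when its extent is
    extreme against the permutation distribution of the maximum cluster size
    (Monte-Carlo p <= cluster_alpha, plus-one estimator, i.e. it exceeds the
    1 - alpha quantile of that distribution up to tie handling).
    """
    params = params or ALEParams()
    null = voxel_null(table, grid, params.kernel_fwhm, params.n_perm, params.rng_seed)
    n_perm = params.n_perm
    mask_flat = np.flatnonzero(grid.mask.ravel())

    # per-permutation p-values by ranking within each voxel's null column;
    # count of perms >= value k (excluding k) is n_perm - rank_min(k), so the
    # plus-one p of perm k is (n_perm - rank_min + 1) / (n_perm + 1)
    ranks = stats.rankdata(null.perm_values, method="min", axis=0)
    perm_p = (n_perm - ranks + 1.0) / (n_perm + 1.0)

    order = {6: 1, 18: 2, 26: 3}[params.connectivity]
    structure = ndimage.generate_binary_structure(3, order)
    max_sizes = np.zeros(n_perm, dtype=int)
    vol = np.zeros(grid.shape, dtype=bool)
    for k in range(n_perm):
        vol[:] = False
        vol.ravel()[mask_flat[perm_p[k] < params.voxel_p_threshold]] = True
        labels, n = ndimage.label(vol, structure=structure)
        if n:
            max_sizes[k] = int(np.bincount(labels.ravel())[1:].max())

    supra = (null.voxel_p < params.voxel_p_threshold) & grid.mask
    clusters: list[Cluster] = []
    for idx in find_clusters(supra, params.connectivity):
        size = len(idx)
        p_clu = (1.0 + int((max_sizes >= size).sum())) / (n_perm + 1.0)
        if p_clu <= params.cluster_alpha:
            vals = null.observed[tuple(idx.T)]
            peak_mm = grid.voxel_to_mm(idx[int(np.argmax(vals))].astype(float))
            clusters.append(Cluster(indices=idx, size=size, peak_mm=np.asarray(peak_mm), p=p_clu))
    clusters.sort(key=lambda c: -c.size)
    return ALEResult(grid=grid, ale=null.observed, voxel_p=null.voxel_p,
                     clusters=clusters, params=params.to_dict())
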