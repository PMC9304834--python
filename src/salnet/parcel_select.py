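"""Overlap scoring of parcellation regions against an ALE result.

percentage overlap = (parcel voxels inside the ALE mask) / (parcel voxels);
a region is included when its fraction strictly exceeds the threshold
(default 0.10, i.e. "more than 10%"). The ALE mask may be either the union of
spheres placed at significant-cluster peaks or the cluster voxels themselves.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ale_meta import ALEResult
from .grid import VoxelGrid

__all__ = [
    "ParcellationVolume", "ParcelSelection",
    "sphere_union_mask", "overlap_fraction", "select_parcels",
]


@dataclass
class ParcellationVolume:
    grid: VoxelGrid
    labels: np.ndarray                      # int, 0 = background
    name_map: dict[int, str]                # label -> region name
    cluster_map: dict[str, str] = field(default_factory=dict)  # region -> anatomical cluster

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.shape != self.grid.shape:
            raise ValueError("labels shape mismatch")
        present = set(np.unique(self.labels)) - {0}
        unnamed = present - set(self.name_map)
        if unnamed:
            raise ValueError(f"labels without a name: {sorted(unnamed)}")

    @property
    def regions(self) -> list[str]:
        return [self.name_map[k] for k in sorted(self.name_map)]

    def region_mask(self, region: str) -> np.ndarray:
        labels = [k for k, v in self.name_map.items() if v == region]
        if not labels:
            raise KeyError(f"unknown region {region!r}")
        return np.isin(self.labels, labels)

    def names_to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"name_map": {str(k): v for k, v in self.name_map.items()},
                       "cluster_map": self.cluster_map}, fh, indent=1)

    @staticmethod
    def names_from_json(path) -> tuple[dict[int, str], dict[str, str]]:
        with open(path) as fh:
            d = json.load(fh)
        return {int(k): v for k, v in d["name_map"].items()}, d.get("cluster_map", {})


@dataclass
class ParcelSelection:
    fractions: dict[str, float]
    included: list[str]
    threshold: float = 0.10

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r, f in sorted(self.fractions.items()):
            hemi, base = (r[0], r[2:]) if r[:2] in ("L_", "R_") else ("", r)
            rows.append({"region": base, "hemisphere": hemi, "fraction": f,
                         "included": r in set(self.included)})
        return pd.DataFrame(rows)


def sphere_union_mask(peaks: list[tuple], grid: VoxelGrid) -> np.ndarray:
    """Boolean volume: voxel centers within radius r of any (mm peak, r) pair."""
    out = np.zeros(grid.shape, dtype=bool)
    idx = np.indices(grid.shape).reshape(3, -1).T
    centers = grid.voxel_to_mm(idx.astype(float))
    for peak, r in peaks:
        if r <= 0:
            raise ValueError("sphere radius must be positive")
        peak = np.asarray(peak, dtype=float)
        if grid.nearest_voxel(peak) is None:
            import logging
            logging.getLogger(__name__).warning("peak %s outside grid; sphere clipped", tuple(peak))
        d2 = ((centers - peak) ** 2).sum(axis=1)
        out.ravel()[d2 <= r * r] = True
    return out


def overlap_fraction(region: str | int, parc: ParcellationVolume,
                     ale_mask: np.ndarray) -> float:
    """|region voxels inside ale_mask| / |region voxels|."""
    ale_mask = np.asarray(ale_mask, dtype=bool)
    if ale_mask.shape != parc.grid.shape:
        raise ValueError("ALE mask grid does not match parcellation grid")
    if isinstance(region, (int, np.integer)):
        region_mask = parc.labels == int(region)
    else:
        region_mask = parc.region_mask(region)
    n = int(region_mask.sum())
    if n == 0:
        raise ValueError(f"region {region!r} is empty")
    return float((region_mask & ale_mask).sum()) / n


def select_parcels(parc: ParcellationVolume, ale_result: ALEResult,
                   mask_source: str = "spheres", threshold: float = 0.10,
                   sphere_radius_mm: float = 3.0) -> ParcelSelection:
    """Score every region and apply the strict >threshold inclusion rule.

    mask_source 'spheres' places a sphere at each significant-cluster peak;
    'clusters' uses the significant-cluster voxels, resampled nearest-neighbour
    onto the parcellation grid when the grids differ.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0,1)")
    if mask_source == "spheres":
        peaks = [(c.peak_mm, sphere_radius_mm) for c in ale_result.clusters]
        ale_mask = sphere_union_mask(peaks, parc.grid)
    elif mask_source == "clusters":
        src = np.zeros(ale_result.grid.shape, dtype=bool)
        for c in ale_result.clusters:
            src[tuple(c.indices.T)] = True
        if (parc.grid.shape == ale_result.grid.shape
                and np.allclose(parc.grid.affine, ale_result.grid.affine)):
            ale_mask = src
        else:  # nearest-neighbour resample onto the parcellation grid
            idx = np.indices(parc.grid.shape).reshape(3, -1).T
            mm = parc.grid.voxel_to_mm(idx.astype(float))
            sv = np.rint(ale_result.grid.mm_to_voxel(mm)).astype(int)
            ok = np.all((sv >= 0) & (sv < np.asarray(ale_result.grid.shape)), axis=1)
            vals = np.zeros(len(idx), dtype=bool)
            vals[ok] = src[tuple(sv[ok].T)]
            ale_mask = vals.reshape(parc.grid.shape)
    else:
        raise ValueError(f"unknown mask_source {mask_source!r}")

    fractions = {r: overlap_fraction(r, parc, ale_mask) for r in parc.regions}
    included = [r for r in parc.regions if fractions[r] > threshold]
    return ParcelSelection(fractions=fractions, included=included, threshold=threshold)
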