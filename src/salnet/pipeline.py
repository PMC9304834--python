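"""End-to-end orchestration: foci -> ALE -> parcel selection -> tracking -> stats.

One YAML/derived config drives every stage; a root seed deterministically
spawns per-stage seeds. Stage outputs are cached on disk under a
content-addressed key (stage name + parameters + upstream keys), so rerunning
with one changed tunable recomputes only the downstream stages.
"""
from __future__ import annotations

import hashlib
import json
import logging
import pickle
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .ale_meta import ALEParams, cluster_inference
from .connectome_stats import aggregate_counts, build_network, round_half_up
from .foci_io import parse_foci_table, packaged_foci_path
from .grid import VoxelGrid, mni_grid
from .parcel_select import ParcellationVolume, select_parcels
from .synthetic_data import BundleSpec, FociSpec, gen_cohort, gen_foci, gen_parcellation, synthetic_grid
from .tractography import TrackingParams, subject_connectome

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_all"]


@dataclass
class RunConfig:
    out_dir: str = "salnet_run"
    seed: int = 0
    # inputs: either file paths or an inline synthetic-data description
    foci_tsv: str | None = None          # None -> packaged transcription
    parc_labels_nii: str | None = None
    parc_names_json: str | None = None
    field_paths: list = field(default_factory=list)  # [{subject, peaks, mask}]
    synthetic: dict | None = None
    # ALE tunables
    kernel_fwhm: float | None = None
    n_perm: int = 1000
    cluster_alpha: float = 0.05
    voxel_p: float = 0.001
    connectivity: int = 26
    ale_spacing_mm: float = 2.0
    # parcel selection
    overlap_threshold: float = 0.10
    mask_source: str = "spheres"
    sphere_radius_mm: float = 3.0
    # tracking
    angular_threshold_deg: float = 45.0
    step_mm: float = 1.5
    max_len_mm: float = 800.0
    min_len_mm: float = 1.0
    n_seeds: int = 1_000_000
    # stats
    n_subjects: int = 25
    min_edge_strength: float = 10.0

    def __post_init__(self):
        if not 0 < self.voxel_p < 1:
            raise ValueError("voxel_p must be in (0,1)")
        if not 0 < self.cluster_alpha < 1:
            raise ValueError("cluster_alpha must be in (0,1)")
        if not 0 < self.overlap_threshold < 1:
            raise ValueError("overlap_threshold must be in (0,1)")
        if self.n_perm < 1 or self.n_seeds < 1 or self.n_subjects < 1:
            raise ValueError("n_perm, n_seeds and n_subjects must be >= 1")
        # construct early so invalid tracking tunables fail before any compute
        TrackingParams(angular_threshold_deg=self.angular_threshold_deg,
                       step_mm=self.step_mm, max_len_mm=self.max_len_mm,
                       min_len_mm=self.min_len_mm, n_seeds=self.n_seeds)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))


def _key(stage: str, params: dict, upstream: str = "") -> str:
    blob = json.dumps({"stage": stage, "params": params, "up": upstream},
                      sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


class _Cache:
    def __init__(self, root: Path):
        self.root = root
        root.mkdir(parents=True, exist_ok=True)
        self.hits: dict[str, bool] = {}

    def get_or_compute(self, stage: str, key: str, fn):
        path = self.root / f"{stage}-{key}.pkl"
        if path.exists():
            self.hits[stage] = True
            with open(path, "rb") as fh:
                return pickle.load(fh)
        self.hits[stage] = False
        value = fn()
        with open(path, "wb") as fh:
            pickle.dump(value, fh)
        return value


def _load_synthetic(cfg: RunConfig, seeds: dict):
    syn = cfg.synthetic
    g = syn.get("grid", {})
    grid = synthetic_grid(g.get("spacing_mm", 1.0), tuple(g.get("shape", (80, 96, 80))))
    parc = gen_parcellation(grid, [
        (p[0], p[1], np.asarray(p[2], float), float(p[3])) for p in syn["parcels"]
    ])
    bundles = [BundleSpec(**b) for b in syn.get("bundles", [])]
    fields, truth = gen_cohort(bundles, parc, syn.get("n_subjects", cfg.n_subjects),
                               seed=seeds["cohort"])
    fspec = syn.get("foci", {})
    loci = fspec.get("loci", "bundle_parcel_centers")
    if loci == "bundle_parcel_centers":
        names = sorted({n for b in bundles for n in (b.region_a, b.region_b)})
        loci = []
        for n in names:
            for hemi in ("L", "R"):
                mask = parc.region_mask(f"{hemi}_{n}")
                loci.append(parc.grid.voxel_to_mm(np.argwhere(mask).astype(float)).mean(axis=0))
    table = gen_foci(FociSpec(
        loci=[np.asarray(p, float) for p in loci],
        n_studies=fspec.get("n_studies", 12),
        subjects_range=tuple(fspec.get("subjects_range", (14, 40))),
        jitter_sigma=fspec.get("jitter_sigma", 2.0),
        foci_per_study_per_locus=fspec.get("foci_per_study_per_locus", 1),
        background_foci=fspec.get("background_foci", 0),
        seed=seeds["foci"]), grid)
    return grid, parc, fields, truth, table


def run_all(config: RunConfig) -> dict:
    """Execute all stages in order and write a machine-readable report.

    Identical config + seed yields an identical report body (no timestamps).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cache = _Cache(out / "cache")
    ss = np.random.SeedSequence(config.seed).spawn(4)
    seeds = {name: int(s.generate_state(1)[0]) for name, s in
             zip(("foci", "ale", "cohort", "track"), ss)}

    # ---- inputs ------------------------------------------------------------
    if config.synthetic is not None:
        grid, parc, fields, truth, table = _load_synthetic(config, seeds)
        foci_key = _key("foci", {"synthetic": config.synthetic, "seed": seeds["foci"]})
    else:
        import nibabel as nib
        from .tractography import OrientationField
        foci_path = config.foci_tsv or str(packaged_foci_path())
        table = parse_foci_table(foci_path)
        foci_key = _key("foci", {"sha": hashlib.sha256(Path(foci_path).read_bytes()).hexdigest()})
        if not (config.parc_labels_nii and config.parc_names_json):
            raise ValueError("parcellation inputs required when synthetic is not set")
        img = nib.load(config.parc_labels_nii)
        labels = np.asanyarray(img.dataobj).astype(int)
        name_map, cluster_map = ParcellationVolume.names_from_json(config.parc_names_json)
        pgrid = VoxelGrid(shape=labels.shape, affine=img.affine, mask=labels >= 0)
        parc = ParcellationVolume(grid=pgrid, labels=labels, name_map=name_map,
                                  cluster_map=cluster_map)
        grid = mni_grid(config.ale_spacing_mm)
        fields = []
        for item in config.field_paths:
            pk = np.asanyarray(nib.load(item["peaks"]).dataobj)
            mk = np.asanyarray(nib.load(item["mask"]).dataobj) > 0
            fg = VoxelGrid(shape=mk.shape, affine=nib.load(item["mask"]).affine, mask=mk)
            fields.append(OrientationField(grid=fg, peaks=pk.reshape(mk.shape + (-1, 3))))
        truth = None

    table_mni = table.to_mni()

    # ---- ALE ---------------------------------------------------------------
    ale_params = ALEParams(cluster_alpha=config.cluster_alpha,
                           voxel_p_threshold=config.voxel_p, n_perm=config.n_perm,
                           kernel_fwhm=config.kernel_fwhm, rng_seed=seeds["ale"],
                           connectivity=config.connectivity)
    ale_key = _key("ale", ale_params.to_dict(), foci_key)
    ale_result = cache.get_or_compute(
        "ale", ale_key, lambda: cluster_inference(table_mni, grid, ale_params))
    pd.DataFrame([
        {"cluster": i, "size_voxels": c.size, "p": c.p,
         "peak_x": c.peak_mm[0], "peak_y": c.peak_mm[1], "peak_z": c.peak_mm[2]}
        for i, c in enumerate(ale_result.clusters)
    ]).to_csv(out / "ale_clusters.csv", index=False)

    # ---- parcel selection ----------------------------------------------------
    sel_params = {"threshold": config.overlap_threshold, "mask_source": config.mask_source,
                  "sphere_radius_mm": config.sphere_radius_mm}
    sel_key = _key("parcels", sel_params, ale_key)
    selection = cache.get_or_compute(
        "parcels", sel_key,
        lambda: select_parcels(parc, ale_result, mask_source=config.mask_source,
                               threshold=config.overlap_threshold,
                               sphere_radius_mm=config.sphere_radius_mm))
    selection.to_frame().to_csv(out / "parcel_selection.csv", index=False)

    # ---- tracking ------------------------------------------------------------
    tp = TrackingParams(angular_threshold_deg=config.angular_threshold_deg,
                        step_mm=config.step_mm, max_len_mm=config.max_len_mm,
                        min_len_mm=config.min_len_mm, n_seeds=config.n_seeds,
                        rng_seed=seeds["track"])
    track_key = _key("track", {**asdict(tp), "n_fields": len(fields),
                               "cohort_seed": seeds["cohort"]}, sel_key)

    def _track():
        frames = []
        for i, f in enumerate(fields):
            con = subject_connectome(f, parc, tp, subject_id=f"subj{i:02d}")
            frames.append(con.to_frame())
        cols = ["subject", "region_a", "region_b", "hemisphere", "count"]
        if not frames:
            return pd.DataFrame(columns=cols)
        return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(columns=cols)

    counts = cache.get_or_compute("track", track_key, _track)
    counts.to_csv(out / "tract_counts.csv", index=False)

    # ---- stats ----------------------------------------------------------------
    included_base = sorted({n.split("_", 1)[1] if n[:2] in ("L_", "R_") else n
                            for n in selection.included})
    cluster_map = {r: c for r, c in parc.cluster_map.items() if r in included_base}
    stats_params = {"n_subjects": config.n_subjects if config.synthetic is None
                    else config.synthetic.get("n_subjects", config.n_subjects),
                    "min_edge_strength": config.min_edge_strength}
    n_total = int(stats_params["n_subjects"])
    edge_stats = aggregate_counts(
        counts[counts["region_a"].isin(cluster_map) & counts["region_b"].isin(cluster_map)],
        cluster_map, n_total) if len(cluster_map) >= 2 else []
    network = build_network(edge_stats, cluster_map, config.min_edge_strength)
    network.to_frame().to_csv(out / "edge_stats.csv", index=False)
    try:
        import networkx as nx
        nx.write_graphml(network.to_graph(), out / "network.graphml")
    except Exception as exc:  # pragma: no cover
        logger.warning("GraphML export failed: %s", exc)

    report = {
        "version": __version__,
        "config": asdict(config),
        "seeds": seeds,
        "cache_hits": dict(cache.hits),
        "n_studies": table.n_studies,
        "n_foci": table.n_foci,
        "ale": {"n_significant_clusters": len(ale_result.clusters),
                "cluster_sizes": [c.size for c in ale_result.clusters]},
        "selected_parcels": {r: round_half_up(f, 4) for r, f in selection.fractions.items()
                             if r in set(selection.included)},
        "network_edges": [
            {"pair": list(e.pair), "fiber_type": e.fiber_type,
             "left_mean_all": round_half_up(e.left.mean_all),
             "right_mean_all": round_half_up(e.right.mean_all),
             "li": None if e.li is None else round_half_up(e.li),
             "p": None if e.p is None else round_half_up(e.p, 4)}
            for e in network.edges
        ],
    }
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
    return report
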