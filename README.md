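# salnet

Parcellation-based structural-functional network modeling as a tested,
reusable pipeline:

1. **foci_io** — parse study/foci tables (TSV), normalize Talairach
   coordinates to MNI via the Lancaster tal2icbm (SPM) affine, derive
   per-focus sphere radii.
2. **ale_meta** — activation-likelihood-estimation maps (per-study Gaussian
   modeled-activation, complement-product union) with permutation
   cluster-level inference (uniform relocation null, plus-one Monte-Carlo
   p-values, max-cluster-size extent test).
3. **parcel_select** — percentage-overlap scoring of parcellation regions
   against the ALE result (`|parcel ∩ mask| / |parcel|`) with the strict
   >10% inclusion rule; mask from spheres at cluster peaks or from the
   cluster voxels.
4. **tractography** — deterministic streamline tracking on per-voxel
   orientation peaks (45° angular threshold, 1.5 mm steps, 800 mm max /
   1 mm min length), whole-brain seeding, two-ROI tract isolation,
   per-pair counting per hemisphere.
5. **connectome_stats** — presence counts, when-present and across-all-brains
   mean strengths, laterality index `(R−L)/(R+L)`, uncorrected two-sided
   Wilcoxon rank-sum p (exact for combined n ≤ 12), cluster-rule fiber
   taxonomy (FAT / U-fiber / other), and the ≥10-tracts network edge filter.
6. **synthetic_data** — generators for clustered foci tables, mirrored
   blob parcellations, and multi-subject orientation fields with planted
   straight/arc/U-shaped bundles (controllable presence probability and
   left/right density ratio) plus the packaged regression fixtures.
7. **pipeline** — one-config orchestration with per-stage seeds,
   content-addressed stage caching, and a JSON report.

## CLI

One umbrella command, plus each stage group as its own executable:

```sh
foci convert --in foci.tsv --out foci_mni.tsv
ale run --foci foci_mni.tsv --n-perm 1000 --cluster-alpha 0.05 --voxel-p 0.001 --seed 17
parcels select --parc parc.nii.gz --names names.json --clusters ale_out/clusters.csv --threshold 0.10
track run --field subj00_peaks.nii.gz --mask subj00_mask.nii.gz --rois parc.nii.gz --seeds 50000 --seed 7
stats build --counts counts.csv --clusters clusters.json --min-edge 10 --out network/
synth cohort --config synth.yaml --out data/
salnet run --config run.yaml          # full pipeline from YAML
```

Foci tables are TSV (`study_id, task, n_subjects, space, x, y, z,
sphere_volume?`); volumes are NIfTI-1; tabular outputs are CSV; the network
graph is GraphML.

## Notes

- The permutation null replaces the analytic histogram null of the reference
  ALE implementation: it is simpler and testable by exhaustive enumeration,
  at the cost of run time (use `--n-perm`/grid spacing to trade accuracy for
  speed). Kernel width defaults to a per-study FWHM derived from the subject
  count via the published between-subject/between-template uncertainty model;
  pass a fixed `kernel_fwhm` for deterministic oracles.
- The tracker uses nearest-voxel peak lookup with sign disambiguation and no
  direction interpolation, so an exact fine-step integration oracle exists;
  this is a documented divergence from interpolating implementations.
- Synthetic bundle density asymmetry is planted as parallel tube copies cut
  at a common centerline arclength, so expected streamline-count ratios equal
  the copy-count ratio exactly.
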