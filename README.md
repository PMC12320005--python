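# strokefc

Lesion-aware resting-state fMRI denoising and connectivity evaluation for
stroke cohorts: stroke-specific confound modelling (lesion-adjusted tissue
masks, anatomical CompCor, lesion-overlap ICA regressors), hemodynamic lag
QC, three denoising pipeline presets, Ledoit-Wolf functional connectivity,
and the evaluation metrics used to compare pipelines (positive/negative
mean strength of lesioned regions, within- vs between-network contrast,
modularity Q) — plus a synthetic-subject generator so the whole chain is
testable without any imaging data.

## Layout

| module | what it does |
| --- | --- |
| `strokefc.io_core` | NIfTI / TSV / JSON I/O, `VolumeImage` / `SubjectContext` / `ConfoundsTable` types, grid validation |
| `strokefc.synthdata` | synthetic stroke subjects with known ground truth (network structure, lesion artifact, lag field, motion) |
| `strokefc.confounds` | motion expansion (24 params), FD (Power & Jenkinson), DVARS, outlier flags, tissue/global signals, aCompCor, lesion ICA, cosine drift |
| `strokefc.lagmap` | 0.009–0.09 Hz band-pass, GM reference, voxelwise lagged cross-correlation (±4 TR), hemispheric 1-s exclusion gate |
| `strokefc.denoise` | `CompCorGS` / `CompCorLesionGS` / `ICLesionCompCorGS` design matrices and confound regression |
| `strokefc.connectivity` | atlas ROI extraction, Ledoit-Wolf (or sample) correlation, lesion seed-to-voxel maps |
| `strokefc.metrics` | lesion-overlap regions, mean strengths, FCC rank-sum Z, Louvain modularity Q, pipeline comparison tables |

## CLI

Everything operates on a subject directory (NIfTI volumes + `motion.tsv` +
`networks.tsv` + `subject.json`), which `strokefc synth` can generate:

```bash
strokefc synth work/ --seed 3 --lesion-voxels 60 --contaminated-regions 3
strokefc confounds work/sub-001 --variant lesion_adjusted --lesion-ica
strokefc lagmap work/sub-001                       # writes lag NIfTIs + QC JSON
strokefc denoise work/sub-001 --pipeline iclesioncompcorgs
strokefc connectivity work/sub-001 \
    --bold work/sub-001/denoised_ICLesionCompCorGS.nii --seed-map
strokefc metrics work/sub-001 \
    --connectivity work/sub-001/connectivity_ledoit_wolf.tsv \
    --pipeline ICLesionCompCorGS
```

`--no-gsr` on `denoise` drops the global-signal group for sensitivity
analyses.

## Notes

- Inputs are assumed pre-aligned on one voxel grid (fMRIPrep-style
  derivatives); no resampling or registration is performed.
- Masks are binarized at 0.99 tissue probability with a dilated-GM
  exclusion; the lesion-adjusted variant folds the lesion into the CSF
  mask and removes it everywhere else.
- ICA components are flagged as noise when their z-scored spatial map
  (|z| ≥ 2) overlaps the lesion by ≥ 5% (component-referenced, inclusive);
  if nothing is flagged the ICA pipeline degrades exactly to its non-ICA
  counterpart.
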