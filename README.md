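# amypipe

Amyloid-PET quantification under a factorial family of image-processing
pipelines, with a synthetic-cohort generator carrying exact ground truth.

Amyloid burden estimated from PET is not a single number: it depends on
the processing choices made before any voxel is averaged.  `amypipe`
implements the full cross product of three such choices —

* **analysis space**: `native` (subject space) or `standard` (template
  space);
* **spatial transform**: `MAPa` (template matching, amount-preserving /
  Jacobian-modulated), `MAPc` (same estimated warp,
  concentration-preserving), or `USM` (unified segmentation);
* **grey-matter definition**: `MRn` (segment the native MRI), `MRs`
  (warp the MRI, segment in standard space; standard-space analyses
  only), or `TEs` (template GM map) —

giving 15 valid pipelines, and quantifies each with five metrics:
mean SUVR over GM (`suvr_mean`), mean SUVR over amyloid-positive GM
(`suvr_mean_abeta_pos`), amyloid-positive volume (`abeta_volume_ml`),
amyloid fraction of GM volume (`afv`), and total amyloid burden
(`tab_ml` = positive-region mean × positive volume).  Positivity is
SUVR ≥ 1.5 by default (1.2 as a sensitivity setting).  Cohort tables are
compared with cluster-robust GEE contrasts.

Because real scans cannot ship with code, the package includes a
**phantom**: an analytic brain template (cortical ribbon, white matter,
ventricles, disjoint cerebellar reference region) from which whole
cohorts are synthesised — subject-specific invertible deformations,
geometric atrophy and spherical amyloid lesions for the patient group,
PSF blur, noise, bias fields and small rigid misalignments — with the
true deformation, tissue maps and noiseless SUVR field retained, so
every estimate can be checked against truth.  See
[docs/methods.md](docs/methods.md) for the models and assumptions.

## Worked example

```python
from amypipe.phantom import PhantomParams, make_template, synthesize_cohort
from amypipe.pipelines import PipelineRunner, enumerate_pipelines
from amypipe.stats import compare_main_pipelines

params = PhantomParams(n_ad=2, n_hc=2, seed=7,
                       grid_shape=(48, 48, 48), spacing_mm=2.0)
template = make_template(params.grid_shape, params.spacing_mm)
subjects, manifest = synthesize_cohort(template, params)

runner = PipelineRunner(template)
table = runner.run_cohort(subjects, enumerate_pipelines())

cols = ["subject_id", "diagnosis", "space", "transform", "gm_def",
        "suvr_mean", "abeta_volume_ml"]
print(table[cols].head(8).to_string(index=False,
                                    float_format=lambda v: f"{v:.3f}"))

main = compare_main_pipelines(table, metrics=("suvr_mean",))
row = main.iloc[0]
print(f"\nstandard vs native (USM+MRn) suvr_mean: "
      f"{row['diff_pct']:+.2f}%  ({row['tier']}, n={row['n']})")
```

Output (about a minute on one CPU):

```
subject_id diagnosis    space transform gm_def  suvr_mean  abeta_volume_ml
      AD01        AD   native      MAPa    MRn      1.083            6.408
      AD01        AD   native      MAPa    TEs      1.075            7.488
      AD01        AD   native      MAPc    MRn      1.083            6.408
      AD01        AD   native      MAPc    TEs      1.075            7.488
      AD01        AD   native       USM    MRn      1.094            6.496
      AD01        AD   native       USM    TEs      0.950            5.648
      AD01        AD standard      MAPa    MRn      0.957            4.872
      AD01        AD standard      MAPa    TEs      0.944            5.512

standard vs native (USM+MRn) suvr_mean: +0.47%  (N.S., n=4)
```

Even on four synthetic subjects the pipeline dependence is visible: the
same scan yields amyloid-positive volumes from 4.9 to 7.5 ml depending
on space, transform and GM definition.

## Command line

```bash
# synthesize a cohort (NIfTI volumes + manifest + params.json)
amypipe phantom make --n-ad 2 --n-hc 2 --grid 48 --spacing 2.0 \
    --seed 7 --out cohort/

# run all 15 pipelines and write the metric table + contrast CSVs
amypipe run --cohort cohort/ --threshold 1.5 --out results/metrics.csv
```

## Reproduction

The end-to-end acceptance run synthesises the default study cohort
(12 AD + 16 HC) at a reduced 48³ / 2 mm grid, executes all 15 pipelines,
and writes the headline quantities (group means, within-subject
coefficients of variation across pipelines, factor contrasts, the
main-pipeline paired comparison, and amyloid-volume recovery against
ground truth) as JSON:

```bash
python scripts/acceptance.py --seed 1 --out acceptance.json
```

All randomness derives from `--seed`; the run takes about 7 minutes on
one CPU.  The test suite (`python -m pytest -q tests/`)
checks the same claims in finer grain: conservation laws of warping,
statistical oracles (GEE vs pooled OLS, analytic Jacobians, bootstrap
vs sandwich SEs, type-I calibration), degenerate-subject behaviour,
parameter recovery on phantoms, cohort-level effect directions, and
structural invariants of the factorial table.
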