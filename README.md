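# pvceval

Evaluation of PET partial-volume-correction (PVC) methods and
linear mixed-effects (LMEM) analysis of longitudinal tau-PET SUVR,
exercised end-to-end on synthetic digital brain phantoms and simulated
longitudinal cohorts with known ground truth.

The package provides:

* **`pvceval.phantom`** — digital brain phantoms: nested-shell label maps
  (WM core, cortical sectors, CSF/meninges/skull shells, cerebellar
  reference), piecewise-constant activity painting, isotropic Gaussian PSF
  blurring (zero-padded FFT convolution), multiplicative noise, and
  longitudinal series with gray-matter atrophy (erosion into CSF) and
  exponential per-label activity change.
* **`pvceval.pvc`** — the five corrections: Meltzer 2-compartment,
  Müller-Gärtner 3-compartment (eroded-WM estimate, CSF assumed zero),
  van Cittert iterative deconvolution, geometric transfer matrix (all
  non-background compartments, condition-number guarded), and
  region-based voxelwise (RBV) applied after GTM.
* **`pvceval.roi`** — composite ROI means, SUVR against an inferior
  cerebellar reference, quartile tau-level stratification (with fixed
  1.30/1.75 threshold override), annualized percent change, centiloid
  amyloid classification.
* **`pvceval.cohort`** — synthetic long-format longitudinal cohorts with
  per-subject random intercepts/slopes on log SUVR, jittered visit
  schedules with dropout, and covariates; presets for a single-site
  natural-history-like study (0/26/52/78 weeks) and a multisite
  trial-like study (0/49/73 weeks).
* **`pvceval.lmem`** — mixed models `lnSUVR ~ covariates + time × group +
  (1|subject) + (−1 + time|subject)`: residual %CV, slope-contrast
  t-scores (1.96 threshold), slope-derived annualized %ΔSUVR, per-subject
  changes from BLUPs, longitudinal effect sizes, parametric bootstrap
  CIs, Spearman baseline-vs-change correlations, and the per-method
  variability/separability tradeoff table.
* **`pvceval.pipeline` / `pvceval.cli`** — orchestration with a
  deterministic, checksummed run manifest.

## CLI

```bash
pvceval simulate-phantom --grid 64 --voxel-mm 2 --fwhm-mm 8 \
    --atrophy-per-year 0.05 --times 0,0.5,1,1.5 --seed 1 --out-dir phantom/
pvceval pvc --method gtm --fwhm-mm 8 \
    --labels phantom/labels_t0.nii --pet phantom/pet_t0.nii --out gtm.json
pvceval quantify --pet phantom/pet_t0.nii --labels phantom/labels_t0.nii \
    --out scans.csv
pvceval simulate-cohort --study nhs --seed 1 --out-dir cohort/
pvceval fit --scans cohort/scans.csv --subjects cohort/subjects.csv \
    --roi WCG --out fit.json
pvceval evaluate --scans all_methods.csv --subjects cohort/subjects.csv \
    --out-prefix eval
pvceval reproduce --study nhs --seed 7 --out-dir run/
```

`reproduce` chains phantom → PVC → quantify → cohort → fit → evaluate
and writes `manifest.json` with a checksum per artifact; re-running with
the same seed and configuration reproduces byte-identical CSV/JSON
outputs.

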