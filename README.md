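# petrad

A tested, reusable pipeline for PET/CT-based binary outcome prediction in
head-and-neck cancer style studies, exercised end-to-end on synthetic
phantom cohorts:

* **synthdata** — phantom PET (SUV) / CT (HU) volumes with deformable
  tumor and nodal masks, clinical covariates with configurable marginals,
  and binary OS/DFS endpoints drawn from a logistic model with planted
  effects (every planted parameter is recorded for recovery tests).
* **imaging** — CT soft-tissue windowing (center 70 HU, width 200 HU),
  PET SUV clipping/scaling, cohort-derived SUV cutoff, VOI cropping, and
  the standard PET parameters SUV_peak (1 cm³ sphere), MTV (50 % of
  SUV_peak) and TLG.
* **radiomics** — mesh/eigenvalue shape descriptors, first-order
  statistics, GLCM / GLSZM / GLRLM texture features, 3D local binary
  pattern histograms, discretization and exact-duplicate removal — each
  texture family validated against brute-force enumeration oracles.
* **tabular** — the 14-column clinical/PET design matrix (D1) with site
  one-hot encoding and dichotomized groups, leakage-free z-score
  standardization, and D1/D2/D1+D2 assembly with feature selections.
* **rent** — repeated elastic net stability feature selection (ensemble of
  elastic-net logistic models on random subsets; nonzero-frequency,
  sign-consistency and t-test criteria) plus the brute-force wrapper over
  repeated stratified 5×20 cross-validation (100 selection sets per
  hyperparameter combination).
* **models** — M1 logistic regression, M2 random forest, M3/M4 fully
  connected networks (M4 with explicit pairwise interactions), and a
  downscaled 3D CNN with mobile-inverted-bottleneck blocks and
  squeeze-excitation (M5–M7 channel variants). The neural models run on a
  small numpy autograd engine in `petrad.nn` — no GPU framework needed.
* **evaluate** — stage-stratified folds, nested 5-fold cross-validation
  with validation-fold rotation (20 models, ensemble-averaged test
  predictions), external-cohort ensembling, and class-balanced bootstrap
  metrics (accuracy, AUC, scaled MCC, per-class F1, precision, recall,
  specificity).
* **explain** — gradient saliency and VarGrad heatmaps (variance over 20
  noisy-input saliency maps), with quantitative stratification by SUV
  bins, HU bins and tumor/node/other location, plus overlay rendering.

## CLI

```bash
petrad simulate  --n-patients 25 --grid 64 --seed 1 --out runs/cohort
petrad petparams --cohort runs/cohort --out runs/petparams.csv
petrad features  --cohort runs/cohort --out-dir runs/features
petrad select    --features-csv runs/features/d1.csv --cohort runs/cohort \
                 --endpoint dfs --out runs/rent.json
petrad train     --features-csv runs/features/d1.csv --cohort runs/cohort \
                 --model M1 --out runs/metrics/m1.json
petrad explain   --cohort runs/cohort --endpoint dfs --out runs/vargrad.json
petrad report    --run-dir runs/metrics --out runs/report.csv
```

Volumes are NIfTI (1 mm isotropic by default), tables are CSV, configs are
YAML, results are JSON/CSV; each command appends to a line-structured
`run.log` with ISO timestamps, seeds and parameters.

## Notes and conventions

* Sphere membership for SUV_peak is by voxel-center distance with the
  radius solving (4/3)πr³ = 1000 mm³; candidate centers are the voxel
  centers inside the tumor mask.
* Radiomics are computed on raw HU/SUV; windowing and clipping feed only
  the CNN inputs.
* Percentiles use numpy's linear interpolation; z-scores use the sample
  standard deviation; duplicate feature columns are dropped only on exact
  equality.
* RENT thresholds default to tau1 = tau2 = 0.9 and a one-sided t-test at
  alpha = 0.05; the per-model subsets are stratified 80 % draws.
* Balanced bootstrap replicates draw `min(class counts)` patients per
  class with replacement; degenerate metrics are reported as 0 and
  flagged.
* Seeded runs are bit-reproducible in single-threaded execution.
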