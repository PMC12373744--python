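# tremornet

Morphometric network analysis toolkit for separating tremor phenotypes
(tremor-dominant parkinsonism, TD, vs essential tremor, ET, vs healthy
controls, HC) from cortical thickness and subcortical volume tables:

- **Group morphometry** — vertex-wise GLM contrasts with Monte-Carlo
  cluster-size correction, subcortical ANCOVA with Benjamini–Hochberg FDR
  across structures and Bonferroni post-hoc contrasts, summary-statistic
  group tests, exact-binomial forward-inference enrichment, early-stage
  subgroup filters.
- **SCN** — seed-based structural covariance: a seed × group interaction
  GLM per vertex (Fisher-z correlation difference as a cross-check) with
  Gaussian-random-field cluster-level correction or a permutation fallback.
- **CaSCN** — causal structural covariance networks: patients ordered by
  disease duration into a pseudo-time series, bivariate signed-path
  Granger coefficients vertex-wise (positive values z-scored,
  max-statistic permutation control, clusters > 10 vertices) and
  ROI-to-ROI, thresholded into a directed network with binary in/out
  degrees and hub reporting.
- **Classifier** — stratified 3:1 split, repeated-LASSO stability
  selection (penalty by 10-fold CV, row subsampling per repeat, count or
  top-30% selection), five learners (RF + linear/poly/RBF/sigmoid SVM)
  tuned by inner 10-fold CV, and bootstrap-resampled AUC on the test set.
- **Synthetic cohorts** — every stage is exercisable without any data
  download: grid-graph atlases, spatially smooth thickness noise,
  duration-lagged cascading regional effects, group-shifted subcortical
  volumes and clinical covariates, all reproducible from one seed.

The atlas is an abstract labeled graph (a 2D grid by construction), so all
spatial operations — smoothing, smoothness (FWHM) estimation, cluster
extraction, random-field inference — are defined on graph adjacency.

## Command line

`tremornet` exposes one subcommand per stage plus an orchestrated run:

```sh
# paper-shaped synthetic cohort (sizes 69/71/80, shipped spec table1_like.cfg)
tremornet simulate --seed 1 --out cohort/

tremornet group-diff --data cohort/ --patient-group TD --out out/gd
tremornet scn       --data cohort/ --seed-region PCUN.R --patient-group TD --out out/scn
tremornet cascn     --data cohort/ --group ET --seed-region TP.R --out out/cascn
tremornet classify  --data cohort/ --features combined --out out/clf

# full pipeline with manifests + markdown report (scaled demo settings)
tremornet run --demo --out demo_out --master-seed 0
tremornet report --out demo_out
```

Every stage writes CSV/GraphML artifacts plus a JSON manifest (parameters,
stage seed, sha256 of each output); a single master seed derives all stage
seeds, so reruns are hash-identical.

Cohort generation is driven by a YAML spec (see
`src/tremornet/data/table1_like.cfg` for the default, which transcribes the
reference cohort's group sizes, duration/clinical distributions and
subcortical shifts); pass your own via `tremornet simulate --spec`.

Input tables may be CSV/TSV or the whitespace "stats" dialect
(`# ColHeaders`-declared columns, one file per subject);
`Left-`/`Right-` structure prefixes are mapped onto the canonical
`<Name>.<Hemi>` namespace.

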