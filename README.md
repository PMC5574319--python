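# metapls

OPLS-DA based ¹H-NMR metabolomics analysis toolkit. Implements the full
chemometric chain used in multi-group treatment studies:

- **synthgen** — synthetic study bundles (metabolite tables, Lorentzian
  binned spectra, structural-similarity matrices) with planted ground truth,
  emulating a six-group design (sham NC, model M, four treatments) with
  n = 8 per group and 26 (serum) / 42 (brain) metabolites.
- **preprocess** — spectral region exclusion (default water window
  4.7–5.1 ppm), total-area normalization, and column scaling (center /
  unit-variance / Pareto) with exact inverse transforms.
- **opls** — two-class OPLS-DA (orthogonal deflation + single predictive PLS
  component), stratified cross-validated Q² with a parsimony rule for the
  orthogonal-component count, and label-permutation validation of R²Y/Q²
  with the OLS intercepts of both statistics on the label correlation.
- **markers** — S-plot coordinates (cov/corr of the predictive score with
  each centered variable), VIP scores (mean-square-1 normalized, VIP > 1
  cut), Benjamini–Hochberg step-up adjustment, and fold-change tables with
  Welch t-tests.
- **sus** — shared-and-unique-structure comparison of two models fitted
  against a common reference class, angular region classification
  (diagonal = shared, axes = unique), and Venn-style region counts.
- **network** — per-group Pearson correlation networks thresholded on |r|
  (0.65 serum / 0.85 brain conventions) and the analytic t-transform
  p-value, structural-similarity edges, and up/down node directions;
  GraphML and TSV exports.
- **studymetrics** — edema-corrected infarct-volume percentage
  I% = (Vc − Vi)/Vc × 100.
- **cli** — a `metapls` command with `simulate`, `preprocess`, `fit`,
  `markers`, `sus`, `network`, `infarct` and `run-all` subcommands.

## CLI

Run the whole pipeline on a synthetic bundle (deterministic given the seed):

```bash
metapls run-all --seed 1 --out runs/demo
```

This writes the synthetic tables/spectra, one OPLS-DA model + permutation
scatter + marker table per comparison (NC, HD, Ber, Bai, Jas each vs M),
SUS/Venn outputs for HD vs each treatment, per-group networks, and a
`manifest.json` recording the seed, configuration and its hash. Individual
stages are exposed as subcommands, e.g.:

```bash
metapls simulate --seed 1 --out runs/sim
metapls fit --table runs/sim/metabolite_table.tsv --group HD --out runs/fit
metapls network --table runs/sim/metabolite_table.tsv --group M \
    --reference NC --r-threshold 0.65 --out runs/net
metapls infarct --volumes volumes.tsv
```

Configuration can also be given as YAML (`--config config.yaml`); every
threshold (scaling method, VIP/corr cuts, SUS angles, network thresholds,
permutation count) is a config field.

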