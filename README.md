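# mrkit

Two-sample Mendelian randomization from GWAS summary statistics, built
around the standard five-method analysis of a binary exposure on binary
outcomes:

* **summary_io** — read/write delimited GWAS summary tables with a
  configurable column map, validate records, and harmonize exposure and
  outcome effects onto a common effect allele (strand complementation,
  sign flips, palindromic-SNP policy `drop` or `infer_by_eaf`, full
  audit trail of dropped SNPs).
* **instruments** — genome-wide-significance filtering (p < 5e-8 by
  default) and greedy LD clumping (10 000 kb window, r² > 0.001) against
  a user-supplied LD matrix; distance-only clumping when no matrix is
  given.
* **estimators** — per-SNP Wald ratios; fixed and multiplicative
  random-effects IVW; MR-Egger (slope + intercept, t inference);
  weighted median and weighted mode with parametric-bootstrap SEs;
  per-SNP F statistics. All estimates carry log-OR and OR-scale 95% CIs.
* **diagnostics** — Cochran's Q at the IVW and Egger fits, Egger
  intercept test, leave-one-out IVW, funnel-plot data, and a
  simulation-based global/outlier/distortion outlier analysis
  (PRESSO-style), fully reproducible from a seed.
* **power** — analytic two-sample MR power for a binary outcome and its
  closed-form inverse (minimum detectable OR).
* **synthgwas** — a two-sample summary-statistics generator with known
  ground truth (causal effect, optional directional/balanced pleiotropy,
  InSIDE violation via a Gaussian copula, block-diagonal LD, planted
  outliers) used throughout the test suite.
* **pipeline** — the end-to-end analysis behind the `mrkit` CLI,
  emitting a five-method estimates table, diagnostics JSON/TSVs, a
  harmonization audit, and a run manifest; byte-identical given the same
  config and seed.

## CLI

```sh
# synthetic two-sample data with known truth
mrkit simulate --out-dir sim --seed 1 --n-snps 43 --true-beta -0.005

# full analysis from a YAML config
mrkit run --config analysis.yaml

# analytic power / power curve
mrkit power --n-outcome 180866 --case-fraction 0.5 --r2 0.193 --or 1.04
```

A minimal `analysis.yaml` (paths are resolved relative to the config
file):

```yaml
exposure: sim/exposure.tsv
outcome: sim/outcome.tsv
ld_matrix: sim/ld.tsv        # optional; omit for distance-only clumping
out_dir: out
outcome_name: depression
seed: 20220830
clump: {p_threshold: 5.0e-8, window_kb: 10000, r2_threshold: 0.001}
palindromic: {policy: infer_by_eaf, eaf_window: 0.08}
estimators: {n_boot: 1000, phi: 1.0}
presso: {n_sim: 1000, outlier_alpha: 0.05}
# exposure_columns / outcome_columns map canonical field names to the
# source file's column names, e.g. {snp_id: SNP, pval: P}
```

## Reproducibility notes

* All stochastic procedures (bootstrap SEs, the outlier analysis, the
  generator) are driven by explicit seeds recorded in their outputs.
* `tests/data/fixture` is a committed 31-instrument synthetic data set;
  `tests/data/golden` holds the pipeline outputs of its first verified
  run and is compared byte-for-byte. Regenerate both with
  `python scripts/make_fixture.py`.
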