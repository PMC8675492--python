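# mrkit

Two-sample Mendelian randomization (MR) from GWAS summary statistics:
harmonization of exposure/outcome association tables, instrument-strength
diagnostics, pleiotropy-robust univariable estimators, multivariable MR with
conditional instrument-strength statistics, binary-outcome power
approximations, and a synthetic summary-statistics generator for
simulation-based calibration of every stage.

## Package layout

| module                | contents |
|-----------------------|----------|
| `mrkit.sumstats`      | `VariantAssociation` / `AssociationTable`, TSV reader with column mapping and row-level rejection, SE reconstruction from p-values, result-table writer |
| `mrkit.harmonize`     | allele alignment (swaps, strand flips), palindromic-SNP classification with an EAF ambiguity window, file-based proxy substitution, `harmonize_dataset` |
| `mrkit.qc`            | significance filtering, greedy LD clumping, per-SNP/mean F, I² of instrument strength, variance explained, binary-outcome MR power |
| `mrkit.estimators`    | Wald ratio, IVW (fixed / multiplicative random effects), weighted median with parametric-bootstrap SE, MR-Egger with pleiotropy intercept, Cochran's Q, unit rescaling, odds-ratio conversion |
| `mrkit.multivariable` | multivariable harmonized sets, MV-IVW / MV-Egger, conditional (two-exposure) F-statistic, modified Q propagating exposure-beta uncertainty and phenotypic correlation |
| `mrkit.simulate`      | `SimulationScenario`, `simulate_pair` / `simulate_mv` / `make_negative_control`, Monte-Carlo `calibrate` (bias, coverage, rejection) |
| `mrkit.pipeline`      | YAML-configured exposure×outcome study runner with Bonferroni correction, per-cell failure isolation and a run log |
| `mrkit.cli`           | `mrkit run / simulate / calibrate / harmonize` |

## Quick start

```python
from mrkit import (SimulationScenario, simulate_pair, harmonize_dataset,
                   ivw, weighted_median, mr_egger)

scenario = SimulationScenario(n_snps=100, theta_true=0.2, seed=1)
exposure, outcome, truth = simulate_pair(scenario)
hset = harmonize_dataset(exposure, outcome)
print(ivw(hset))                      # IVW, multiplicative random effects
print(weighted_median(hset, seed=1))  # bootstrap SE, explicit seed
print(mr_egger(hset))                 # slope + pleiotropy intercept
```

### Input format

Tab-separated tables with a header; standard fields `variant_id`,
`effect_allele`, `other_allele`, `eaf`, `beta`, `se`, `pvalue`, `n`
(optional `z`). `.`/empty/`NA` denote missing values. Column names are
remapped via `column_map`, odds-ratio-scale sources are log-transformed with
`or_scale=True`, and a missing `se` column is reconstructed from `beta` and
`pvalue` (below p = 1e-300 a `z` column is required). Proxy maps are TSVs
with columns `missing_id`, `proxy_id`, `r2`, `allele_map` (e.g. `A=G,C=T`).

## CLI

```sh
mrkit run --config study.yaml          # full exposure x outcome grid
mrkit simulate --scenario scen.yaml --out simdir
mrkit calibrate --scenario scen.yaml --methods ivw,median,egger --reps 500 --seed 1
mrkit harmonize --exposure x.tsv --outcome y.tsv --out h.tsv
```

Exit codes: 0 success, 2 configuration/usage error, 3 data error.

A study YAML looks like:

```yaml
exposures:
  - trait_id: sbp
    path: sbp.tsv
    phenotype_sd: 20.1       # mm Hg; enables variance-explained + rescaling
    rescale_unit: 10.0       # extra per-10-unit estimate row
    # instruments: sbp_ids.txt   # or: p_threshold: 5e-8
outcomes:
  - trait_id: total_cancer
    path: total_cancer.tsv
    trait_type: binary
    n_cases: 37387
    n_noncases: 367856
proxy_map: proxies.tsv       # optional
alpha: 0.05
correction: bonferroni       # threshold = alpha / (n_exposures * n_outcomes)
n_boot: 1000
seed: 7
output_dir: out
```

Scenario YAML keys mirror `SimulationScenario` fields (`n_snps`,
`n_exposure`, `n_outcome`, `case_fraction`, `target_r2`, `theta_true`,
`pleiotropy_mean`, `pleiotropy_sd`, `invalid_fraction`,
`inside_violation_rho`, `palindromic_fraction`, `min_effect_z`, `seed`).

## Tests

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria, including
fixed-seed Monte-Carlo calibration checks (~20 s). One strict
weighted-median unbiasedness assertion is expected to fail by design of the
estimator at the configured noise level (see the test docstring). The
criterion-6 integration tests are skipped unless supplementary association
tables are placed under `data/supplementary/` as
`systolic_bp.tsv`, `diastolic_bp.tsv`, `total_cancer_systolic.tsv`,
`total_cancer_diastolic.tsv` in the standard input format above (with
`eaf` populated for the exposure files).

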