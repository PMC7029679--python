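# watershed-sem

A structural-equation-modeling pipeline for hierarchical "watershed"
analyses of fluid intelligence: white-matter tract measures feed
intermediate cognitive endophenotypes (working memory, processing speed),
which feed a downstream fluid-ability factor.

The package provides:

- **`model_spec`** — lavaan-style model syntax (`=~`, `~`, `~~`, equality
  labels, `0*` fixing) compiled to RAM matrices (directed `A`, symmetric
  `S`, filter `F`), with marker-variable scaling, single-indicator latent
  handling, degrees-of-freedom bookkeeping, and necessary-condition
  identification checks.
- **`estimation`** — normal-theory ML for covariance input and
  full-information ML (FIML) for raw data with missingness, with analytic
  gradients, standardized solutions, R², observed-information standard
  errors, and regression-method factor scores.
- **`fit_compare`** — χ², RMSEA with noncentral-χ² confidence bounds, CFI,
  SRMR, AIC/BIC, Akaike weights, nested χ²-difference tests, and a verbal
  good/acceptable/poor fit classification.
- **`watershed_models`** — the full model library: four competing
  measurement models of cognition, constrained cognitive regressions, the
  single-factor white-matter model, the watershed model with alternatives
  A–D and constrained variants, the single-path suppression probe, and an
  end-to-end `run_full_analysis` report generator.
- **`sem_tree`** — SEM trees: recursive age splitting of a focus parameter
  with all other parameters held invariant across groups, scored by k-fold
  cross-validated held-out log-likelihood gain.
- **`synthetic_data`** — a seeded cohort generator mirroring the watershed
  truth (correlated tracts, endophenotypes, fluid factor, task indicators,
  raw reaction-time speed scores, imaging-subset missingness) plus the
  speed-score preprocessing (`y = log(1/x)`, ±2 SD trim).
- **`io_cli`** — CSV/YAML readers and the `watershed` command line.

## Command line

```sh
# generate a synthetic cohort
watershed simulate --n 551 --seed 7 --out cohort.csv

# fit one model (raw CSV, or a covariance CSV via --cov-n)
watershed fit --data cohort.csv --battery calm --model original --out results

# compare measurement models by Akaike weight
watershed compare --data cohort.csv --models single,twoA,twoB,three --out results

# grow a SEM tree for one focus parameter
watershed tree --data cohort.csv --model three --focus "gf~~wm" --covariate age --out results

# full analysis report (JSON + Markdown)
watershed report --data cohort.csv --battery calm --out results/report.json
```

Batteries are built in (`calm`, `nki`) or supplied as YAML naming the task
columns per factor and the ten tract columns. Every run writes a
`manifest.json` recording the config hash, seed, and package version.

## Data formats

- Per-subject data: CSV with a header row, one row per subject, empty cell
  = missing, `.` decimal, UTF-8.
- Covariance input: square CSV with a matching header plus a sample size.
- Model files: plain-text model syntax, one relation per line, `#` comments.
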