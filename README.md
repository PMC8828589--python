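# episelect

Analysis pipeline for field trials of epigenetically diversified crop lines:
two-level percentile selection, multi-environment strategy evaluation,
genotype-by-environment resilience metrics, cold-stress emergence curves,
and reversion-frequency testing — plus a synthetic trial generator so every
stage is testable without external data.

## What it does

- **`synthetic_trials`** — seeded generators for plant-level augmented
  incomplete-block trials (per-line epi-effect mixture, copula-calibrated
  tiller–yield correlation), plot-level two-location lattice trials with
  category effects and line-specific low-input sensitivity, logistic
  emergence time courses, and binomial revertant counts.
- **`selection_engine`** — 30th/70th wild-type percentile cutoffs; Low /
  Medium / High classification of family means and of individual plants
  (boundaries inclusive in Medium); the nine combined categories
  (`LL.LI` … `HL.HI`); evaluation of three selection strategies
  (unselected, line-mean, line + individual) against wild-type checks with
  raw or LS-mean group estimates.
- **`trial_stats`** — per-trait models (`value ~ genotype + block`, block
  random, REML; Poisson log-link for tiller counts; Gamma log-link for
  flowering), line-vs-check LS-mean contrasts, two-sided Fisher exact tests
  (scalar and vectorized-over-margins), reversion frequencies, and moisture
  standardization of plot yields to 140 g/kg.
- **`resilience_metrics`** — percent yield differential between a favorable
  and a stress environment; stable (<30%) / dynamic (>70%) calls;
  per-category differential profiles.
- **`emergence_analysis`** — adjusted emergence (early ÷ standard planting,
  final-count or daywise denominator), trapezoidal area under the emergence
  curve (AUPEC), emergence rate, and group contrasts.
- **`cli_io`** — schema-validated CSV/TSV readers and writers, YAML run
  configuration, and a pipeline orchestrator with a reproducible run log.

## CLI

```sh
episelect simulate --seed 1 --out bundle/           # synthetic trial bundle
episelect classify  --plants bundle/input_plants.csv --cutoffs auto
episelect evaluate  --plots plots.csv --categories cats.csv --env normalN
episelect stats     --plants plants.csv --trait yield --model auto
episelect resilience --plots plots.csv --env-normal normalN --env-low lowN
episelect emergence --table emergence.csv --adjust final
episelect reversion --table reversion_counts.csv
episelect run --config config.yaml                  # full pipeline
```

`episelect run` executes every stage available from the configured inputs,
writes one table per stage plus `run_log.json`, and skips (and records)
stages whose inputs are missing. All randomness flows from the single
config seed; identical config + seed gives identical outputs.

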