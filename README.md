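# latedating

Gestational-age (GA) dating from late-pregnancy fetal biometry, built as a
reusable analysis pipeline:

- **`latedating.dating_equations`** — validation of biometric measurements
  (plausible ranges, replicate summaries) and configuration-driven dating
  equations mapping BPD / HC / FL / AC / TCD (and first-trimester CRL) to GA
  in days. Nomogram coefficients live in `src/latedating/data/equations.yaml`
  as data, not code; swap in transcribed published coefficients by editing or
  pointing to another config file.
- **`latedating.synthetic_cohort`** — seeded generator for three-site cohorts
  with configurable SGA prevalence, between-fetus size variation, growth
  restriction that spares the cerebellum (`sparing_factor`), measurement
  noise, missingness, and loss to follow-up. Growth curves are the numerical
  inverses of the configured dating equations, so noiseless scans round-trip
  exactly.
- **`latedating.agreement`** — Bland–Altman bias, 95% CIs and 95% limits of
  agreement against the gold-standard (CRL-based) GA, the "approximation"
  midpoint statistic, SGA/AGA stratification against a pluggable birthweight
  standard, the >60-day outlier-exclusion rule, and sample-size arithmetic.
- **`latedating.model_derivation`** — candidate GA formulas regressed on
  ln-transformed biometry with participant-clustered robust errors,
  adjusted-R²/AIC reporting, 5-fold (participant-partitioned) and
  leave-one-site-out cross-validation using the standardized error
  `(observed − predicted)² / predicted`, and model selection.
- **`latedating.pipeline` / `latedating.cli`** — orchestration with reason-coded
  exclusion logging, flow summaries, and byte-reproducible TSV reports.

## CLI

```sh
# generate a synthetic cohort as TSV tables
latedating simulate --seed 7 --n-per-site 400 --out scratch/cohort

# full pipeline (simulate/ingest -> validate -> date -> exclude -> agree -> derive)
cat > run.yaml <<EOF
synthetic:
  n_per_site: 400
  seed: 7
EOF
latedating all --config run.yaml --out scratch/results
latedating report --results scratch/results
```

Stage-level subcommands `validate`, `estimate`, `agreement`, and `derive`
operate on existing scan/birth tables; see `latedating <cmd> --help`.

Outputs land as TSV: `agreement.tsv` (estimator × window × {ALL, AGA, SGA}
rows with bias, CI, LOA, approximation at 0.1-day precision),
`model_report.tsv` / `cv_errors.tsv`, `flow_summary.tsv`, `exclusions.tsv`,
plus the cleaned cohort tables. Re-running the same config reproduces
byte-identical files.

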