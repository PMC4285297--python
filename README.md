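# twofoldmi

Two-fold fully conditional specification (FCS) multiple imputation for
longitudinal panel data with intermittent missingness, plus the
apparatus to evaluate it: a synthetic primary-care-style cohort
generator with a consultation-driven MCAR missingness mechanism, an
exponential proportional-hazards substantive model, Rubin's-rules
pooling, and a Monte-Carlo study harness reporting bias, precision,
coverage, relative efficiency and information loss for competing
imputation strategies.

## What is implemented

- `twofoldmi.panel` — panel/outcome data types, validation, long/wide
  CSV readers and writers, complete-records extraction.
- `twofoldmi.imputers` — proper ("Bayesian draw") univariate imputers
  for continuous (normal-linear), binary (logistic) and categorical
  (multinomial-logit) responses, with collinearity pruning and a
  ridge-retry guard against perfect separation; marginal-resampling
  initialisation.
- `twofoldmi.fcs` — the chained-equations engine plus plan builders for
  the *baseline* (first block only) and *full* (all variable-block
  pairs) comparator strategies.
- `twofoldmi.twofold` — the two-fold scheduler: within-time FCS passes
  restricted to a ±τ window of time blocks, nested in among-time sweeps,
  with a time-independent-variable step at the start of every sweep and
  semi-deterministic preprocessing for monotone-constrained categorical
  variables (e.g. "once a smoker, never again a non-smoker").
- `twofoldmi.survival` — exponential proportional-hazards ML fit
  (Newton–Raphson, deterministic start) and covariate-table assembly.
- `twofoldmi.pooling` — Rubin's rules with Barnard–Rubin degrees of
  freedom.
- `twofoldmi.cohort` — synthetic cohort generator (mechanism I:
  time-independent smoking; mechanism II: alternating current/ex-smoker
  trajectories) and the consultation-driven MCAR mechanism.
- `twofoldmi.harness` — replicate → generate → fit full data → impose
  missingness → complete records / baseline FCS / full FCS / two-fold →
  pool → aggregate.

## CLI

```sh
# write a synthetic cohort (long-layout panel CSV + outcome CSV)
twofoldmi simulate --n 5000 --blocks 10 --mechanism I --seed 1 --out data/

# impute it
twofoldmi impute --panel data/panel.csv --outcome data/outcome.csv \
    --method twofold --tau 1 --b-within 5 --b-among 20 --k 5 \
    --seed 1 --out imputed/

# run a Monte-Carlo study (scale < 1 shrinks patients and replications)
twofoldmi run-study --scale 0.05 --seed 1 --out study/
```

`impute --method baseline-fcs|full-fcs` runs the comparator strategies.
A YAML schema (`--schema`) describes custom panels; by default the
built-in cohort schema is used.

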