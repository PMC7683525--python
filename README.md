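# routinestability

Day-to-day behavioral routine stability from passively sensed smartphone
streams, for digital-phenotyping research in serious mental illness.

People's routines — when they call, message, move, sleep, or sit still —
carry clinical signal: routine stability is a common target of behavioral
interventions in schizophrenia-spectrum disorders, but retrospective
questionnaires measure it poorly.  This package computes a **Stability
Index (SI)** directly from minute-resolution passive-sensing streams and
carries it through a full evaluation pipeline: data-quality filtering,
windowed feature extraction, momentary symptom (EMA) scoring, pooled
correlation analysis, and personalized symptom prediction with
gradient-boosted trees.  A synthetic-cohort generator with known ground
truth makes every stage testable without access to clinical data.

## The metric

For behavior *b* on day *d*, with `A_b^d(x)` the activity amount in minute
*x* of the day (*M* = 1440 minutes):

```
C_b^d(x)    = Σ_{i≤x} A_b^d(i) / Σ_{i≤M} A_b^d(i)          normalized cumulative sum
D_b(d1,d2)  = (1/M) Σ_x |C_b^d1(x) − C_b^d2(x)|             day-pair distance
SI_b(P)     = 1 − median{ D_b(i,j) : i,j ∈ P, i ≠ j }       Stability Index
```

SI ∈ (0, 1]; higher means a more repeatable daily timing pattern.  Because
days are compared through cumulative distributions, a schedule shifted by
δ minutes moves the distance by at most δ/M — unlike hourly-histogram
comparisons, which saturate when one event slides across an hour mark.

## Worked example

Run the end-to-end demo: simulate a 13-participant, 365-day cohort with
symptom-coupled routine jitter, extract windowed features, correlate SI
with the EMA composite, and fit the personalized prediction models:

```sh
stability demo --seed 7 --out-dir demo/
```

```
routinestability demo (seed=7, 13 participants, 365 days)

simulated 308021 events, 1263 EMA responses
built 1233 window(s); retained 1233 for 13 participant(s)
defined SI values: 20961 in [0.5003, 0.9972]

Bonferroni-significant SI correlations with the EMA composite:
  incoming_messages: r=-0.313 (corrected p=3.6e-28, n=1233)
  outgoing_messages: r=-0.438 (corrected p=8.5e-58, n=1233)
  call: r=-0.588 (corrected p=1.6e-114, n=1233)
  unlock: r=-0.590 (corrected p=1.9e-115, n=1233)
  ambient_nonvoice: r=+0.580 (corrected p=1e-110, n=1233)
  sleep: r=+0.183 (corrected p=1.7e-09, n=1233)
  walk: r=+0.095 (corrected p=0.014, n=1233)
  still: r=+0.476 (corrected p=1.7e-69, n=1233)

Individual-only GBRT prediction (n_train=5, 10 most recent test points):
  prev_ema: MAE=7.447 CI95=(6.038, 8.869) n=76
  mean_sd: MAE=7.438 CI95=(6.632, 8.378) n=130
  si: MAE=7.890 CI95=(7.076, 8.826) n=130
  si_mean_sd: MAE=7.525 CI95=(6.769, 8.413) n=130
  baseline_population_mean: MAE=8.559 CI95=(7.684, 9.377) n=130
```

Reading the output: the generator couples symptom level to timing jitter
with negative SI–symptom association for messages/calls/unlocks and
positive for stillness and ambient non-voice sound, and the pooled
correlations recover exactly those signs (a couple of uncoupled behaviors
reach nominal significance — the price of overlapping, autocorrelated
windows).  Every feature-based model beats the population-mean baseline,
and the previous-EMA model is only evaluable on the 76 of 130 test points
where a response from exactly 7 days earlier exists — EMA missingness is
37% by design.

The same stages are available as individual subcommands (`simulate`,
`features`, `correlate`, `predict`, `predict-population`, `predict-lead`,
`distances`) and as library functions:

```python
import routinestability as rs

cohort = rs.generate_cohort(rs.default_config(seed=7))
table = rs.retain_participants(
    rs.build_feature_table(cohort.streams, cohort.coverage, cohort.ema))
corr = rs.correlation_table(table, kind="si")
result = rs.run_individual_experiment(table, model="si", n_train=5, seed=7)
```

See `docs/methods.md` for the model, its assumptions, the generator's
design, and known limitations.

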