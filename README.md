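# clockbind

Analysis pipeline for **action binding** measured with a modified Libet-clock
task, including the testing-order (carryover) control and the correlation of
binding strength with delusional ideation — plus a seeded synthetic-cohort
generator so the whole pipeline can be exercised and validated without
access to a real data set.

## The problem

When a voluntary keypress triggers a delayed tone, the perceived time of the
keypress shifts *toward* the tone ("action binding"). The effect is measured
by comparing two conditions: **AO** (action only — silent keypress) and
**AS** (action + sound — keypress followed by a 250 ms tone). In the
modified task, a clock hand rotates with an 1800 ms period and participants
try to press exactly at the 12 o'clock crossing, then judge whether the
press was *before*, *at*, or *after* 12. Only 'at-12' trials enter the
binding analysis: for such a trial with physical press time `t1` and
crossing time `t2`,

```
perceived keypress time = t2 - t1      (positive: awareness lags the press)
actual keypress time    = t1 - t2      (negative: pressed early)
```

and a condition runs until 40 'at-12' trials have been acquired.

The pipeline implements four stages:

1. **Binding.** Per participant, the median 'at-12' perceived time per
   condition; binding = median(AS) − median(AO). Outlier participants are
   excluded with the MAD-median rule on the average of the two condition
   medians `p`: flag `p` when `|p − median(P)| × 0.6745 > 3 × MAD-median`.
   Effect sizes follow `dz = t/√n` (paired) and `ds = t·√(1/n1 + 1/n2)`
   (unpaired, pooled-variance design).
2. **Testing order.** Which condition came first matters: the previously
   tested condition's subjective shift carries over into the first trials of
   the next condition. Diagnosed with per-participant OLS slopes of
   perceived time over 'at-12' trial index and the between-order-group
   binding contrast.
3. **Cut-off scan.** The order contrast is recomputed after dropping the
   first n 'at-12' trials of each condition (n = 0, 1, 2, …); the cut-off
   n\* is the smallest n from which the contrast stays non-significant
   through a stability horizon.
4. **Delusional ideation.** The PDI-21 questionnaire (21 yes/no items, each
   endorsed item adding 1 + three 1–5 ratings; overall score 0–336) is
   correlated, Pearson and one-tailed, with per-participant binding
   *strength* — the trial-level unpaired t of AS vs AO perceived times after
   dropping the first 10 trials per condition — after boxplot-rule outlier
   exclusion, with a seeded percentile-bootstrap 95% CI.

The synthetic generator emulates all of this: per-participant baseline
shifts and binding increments, exponentially decaying asymmetric carryover,
slow common drift, truncated aiming noise producing ~41 ms per-condition
SDs, acquisition-until-40-'at-12'-trials, and PDI scores correlated with
binding strength at a configurable level.

## Worked example

```sh
clockbind simulate --seed 7 --out demo_cohort
clockbind analyze --trials demo_cohort/trials.csv --pdi demo_cohort/pdi.csv \
    --seed 7 --out demo_results
```

prints (this exact output for this seed):

```
Participants: 52 analysed, 0 excluded by the MAD-median rule.
Action binding (whole sample): perceived keypress time AS mean 45.64 ms vs AO mean 22.89 ms; paired t(51) = 7.44, p = 5.54e-10 (one-tailed), dz = 1.03.
Testing-order effect on binding: AO-first mean 25.10 ms vs AS-first 20.40 ms; t(50) = 0.76, p = 0.448 (two-tailed), ds = 0.21.
Leave-first-n scan: order contrast stays non-significant (alpha = 0.05) from n* = 0 through the horizon (30).
Delusional ideation vs binding strength: Pearson r = 0.28 (n = 49), p = 0.025 (greater), bootstrap 95% CI [-0.04, 0.55].
  ledger: 52 after MAD screen - 0 incomplete PDI - 3 boxplot outliers = 49.
```

Reading it: the simulated cohort shows a clear ~23 ms binding effect (AS
later than AO), a small positive order-group difference (single cohorts
rarely resolve the ~2 ms carryover residue that medians leave at n = 0, so
n\* = 0 here), and a positive delusion–binding correlation near the
configured 0.27 with three boxplot exclusions. `demo_results/` also holds
`analysis_bundle.json` (every statistic with provenance metadata),
`order_scan.csv` (one row per n) and `correlation_scatter.csv`.

The library surface mirrors the CLI: `simulate_cohort`, `build_summaries`,
`mad_median_screen`, `binding_estimates`, `cohort_binding_report`,
`leave_first_n_scan`, `cutoff_from_scan`, `delusion_binding_analysis`, …
(see `docs/methods.md` for the model and conventions).

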