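# Methods

## The generative model

The synthetic cohort emulates a two-condition Libet-clock timing task with a
subjective-shift model. Participant `i` in testing-order group AO→AS or
AS→AO performs both conditions in their group's order; within a condition,
let `k` be the number of 'at-12' trials already acquired. The subjective
shift of awareness relative to the physical press on the next trial is

    s = b_i + d_i·[condition = AS] + w·(s_prev_end − s_own_base)·exp(−k/τ) + δ·k

where

* `b_i ~ N(baseline_shift_mean, baseline_shift_sd²)` is the participant's
  baseline shift (defaults 15 ± 25 ms),
* `d_i = binding_mean + binding_sd·ζ_i` is the binding increment added in
  the AS condition (defaults 23 ± 15 ms, `ζ_i` standard normal),
* the carryover term pulls the first trials of the second-tested condition
  toward the asymptotic shift of the first: `s_prev_end` and `s_own_base`
  are the two conditions' asymptotic shifts `b_i + d_i·[AS]` (zero carryover
  for the first-tested condition), `τ` (`carryover_tau`, default 3) is the
  e-folding constant *in acquired 'at-12' trials* — the same index the
  analysis uses — and the weight `w` is direction-specific:
  `carryover_into_ao = 1.0` (a preceding AS condition contaminates AO) and
  `carryover_into_as = 0.0` (no influence the other way), encoding the
  asymmetry the analysis is designed to detect,
* `δ` (`drift_slope`, default +0.3 ms per 'at-12' trial) is a slow common
  drift shared by both conditions.

Aiming/judgement noise is `η ~ N(aim_bias, aim_sd²)` (defaults −10, 60 ms).
The physical press lands at `a = −s + η` relative to the aimed crossing, so
the subjective press position is `q = a + s = η`: the response is *before*
if `q < −θ`, *at* if `|q| ≤ θ`, *after* if `q > θ`, with `θ`
(`response_threshold`) = 80 ms. Consequences that the test suite checks
against closed forms:

* 'at-12' perceived times are `s − η` with `η` truncated to `±θ`; the
  truncated SD at defaults is ≈ 41 ms, matching the measurement precision
  the modified task is designed to reach (the suite requires the simulated
  per-condition SD to fall in 30–55 ms);
* a negative `aim_bias` yields more *before* than *after* responses, and
  mean actual press time is ordered before < at < after;
* noise-free runs (`aim_sd = 0`) reproduce `b_i` and `d_i` exactly, and the
  carryover gap between order groups decays *exactly* geometrically — by
  `exp(−1/τ)` per 'at-12' trial at the trial level, and by `exp(−1/τ)` per
  **two** dropped trials in the median-based leave-first-n scan, because the
  median's window midpoint advances half an index per dropped trial.

Trials are emitted (all three response types) until 40 'at-12' trials exist
(`trials_at12_target`), failing loudly after `max_attempts_per_condition`
(400). Timestamps are cumulative clock time: inter-trial period uniform on
[2000, 2500] ms, hand period 1800 ms, the press aimed at the next full
crossing, 900 ms of post-press rotation; only `t2 − t1` matters downstream.

### Delusional-ideation structure

A latent trait `z_i` correlates with `ζ_i`. The PDI-21 overall score is a
monotone right-skewed (lognormal) transform
`score = clip(round(median·exp(σ·z_i)), 0, 336)` with median 50 and σ =
0.55, giving a cohort mean near 58 and SD near 34 — the range published for
healthy adults. The item-level allocation (which items are endorsed, how the
ratings split) is deterministic given the score and deliberately simple:
only the overall score carries information downstream.

`pdi_binding_rho` (default 0.27) targets the **observable** correlation
between the trait and measured binding strength. Two closed-form attenuation
factors separate that from the latent `z`–`ζ` correlation: the nonlinearity
of the score transform (`a_score = σ/√(exp(σ²)−1)` ≈ 0.93) and the
reliability of the per-participant binding estimate
(`a_bind = binding_sd/√(binding_sd² + 2·sd_trunc²/m)` ≈ 0.82 at defaults,
with `m` the 30 'at-12' trials per condition the standard analysis retains).
The generator divides the target by both, so parameter recovery of the
observable correlation is unbiased by construction rather than by tuning;
the inflated latent correlation is recorded in the ground-truth ledger.

### What the generator does *not* emulate

Reaction-time structure, keypress force, the ~2 ms jitter of the nominal
250 ms sound delay (the sound time never enters the analysis), fatigue or
learning beyond the single linear drift term, non-normal trial noise, and
item-level PDI psychometrics. Passing recovery tests therefore show the
*pipeline* is consistent and calibrated under the assumed structure — not
that real cohorts satisfy that structure.

## Analysis conventions

* **Central tendency.** Participant-level condition summaries use the
  median of 'at-12' perceived times throughout; group summaries use means
  with t-based 95% CIs.
* **Exclusion order.** The MAD-median screen (on the average of the two
  condition medians, constant 0.6745, cutoff 3·MAD, evaluated on the full
  cohort vector including candidates) runs once, before everything else;
  downstream stages never see flagged participants. If MAD = 0 with unequal
  values, everything off the median is flagged with a warning — the rule
  itself degenerates there and the convention is ours.
* **t tests.** Student pooled-variance everywhere (`equal_var` switch
  available): the design is balanced and the `ds` convention is the pooled
  form. Binding contrasts are one-tailed (AS later than AO, the directional
  hypothesis); order, slope and count contrasts two-tailed. Zero-variance
  inputs raise rather than return infinities, and the per-participant
  binding t is set to NaN when trial variance is indistinguishable from
  timestamp round-off.
* **Per-condition order effect.** The "absolute change due to testing
  order" of a single condition is computed as the between-group unpaired t
  on that condition's medians (two-tailed) plus the absolute difference of
  group means; the construction of this check is not uniquely pinned down
  by its usual verbal description, so it is fixed here and labelled in the
  report.
* **Scan and cut-off.** The scan recomputes per-participant binding from
  trials n+1…end (single-trial series allowed at the deepest rows) with the
  exclusion set frozen at n = 0; SE = SD/√group size; the between-group t
  is two-tailed and deliberately uncorrected for multiplicity. The cut-off
  n\* is the smallest n whose p stays above α through the `horizon`
  (default 30, not the deepest possible 39: rows built on a handful of
  trials are too noisy to define "consistently thereafter"). A scan that
  would unbalance the groups stops and records why.
* **Correlation.** Binding strength = trial-level unpaired t (AS vs AO)
  with `n_drop = 10`. Incomplete questionnaires are dropped, then the
  boxplot rule (1.5 × IQR fences; quartiles by linear interpolation between
  order statistics — the flag set can depend on this, so it is fixed) is
  applied to each variable independently and the union excluded; the
  one-tailed p uses the t transform with df = n − 2; the 95% CI is a
  percentile bootstrap over `n_boot = 2000` seeded resamples of pairs
  (plain percentile, not BCa; degenerate resamples are dropped). The union
  reading of the boxplot exclusion is interpretive and documented as such.
* **Determinism.** One seed drives everything. Cohort-level latent draws
  come from a single row-per-participant normal block and per-participant
  trial streams are spawned from the same seed, so participant `i`'s data
  are invariant to cohort size; the analysis derives its bootstrap sub-seed
  from the run seed, so stages re-run in isolation reproduce bit-identical
  artifacts. Every output embeds package version, seed, configuration and
  input checksums.

## Validation problem sizes

The simulation-based checks in `tests/test_acceptance.py` run at the study's
own scale (52 participants, 40 'at-12' trials per condition): 500 seeded
cohorts for null calibration and binding recovery, 200 for order structure
and correlation recovery, 300 bivariate-normal samples (n = 45, 2000
bootstrap resamples) for CI coverage, and 100 for the validity-report
structure — sizes chosen so binomial/Monte-Carlo error is comfortably inside
each acceptance band.

## Known limitations

* With median-based binding and the default transient carryover (τ = 3),
  the expected order-group gap at n = 0 is only ~2 ms — detectable across
  hundreds of seeded cohorts but usually not within one, so single synthetic
  cohorts often yield n\* = 0. Real data with slower or partial decay
  produce the larger gaps that make the scan informative; a larger τ or
  carryover weight does the same in simulation.
* The attenuation correction for `pdi_binding_rho` is first-order: it
  ignores the small extra noise of the t statistic's denominator and the
  effect of boxplot exclusions, which leave the recovered correlation within
  a few hundredths of the target rather than exactly on it.
* The boxplot-union exclusion rule and the per-condition order-effect test
  construction are documented interpretations; alternatives (single-variable
  exclusion, paired constructions) are easy to wire but not exposed as
  options.
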