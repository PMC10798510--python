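# Methods

## Model structure

The analysis couples a 30-day decision tree to a lifetime Markov cohort
model, comparing sutureless/rapid-deployment (SUAVR) with conventional
(CAVR) aortic valve replacement.

### Acute phase (decision tree, `avrcea.tree`)

Four branches: early complication yes/no, death yes/no conditional on the
branch. With complication probability `p_c` and conditional death
probabilities `p_d|c`, `p_d|nc`:

```
p_dead30       = (1 - p_c) * p_d|nc + p_c * p_d|c
p_alive_comp   = p_c * (1 - p_d|c)
p_alive_nocomp = (1 - p_c) * (1 - p_d|nc)
```

The whole cohort accrues the eleven admission cost components at time zero
(surgery precedes any death); the societal perspective adds the direct
non-medical admission costs (transport, food, accommodation, informal care).
Acute QALYs are `u_30d x 30/365.25 x (1 - p_dead30)`; acute life-years credit
survivors with the full 30-day window.

### Lifetime phase (Markov model, `avrcea.markov`)

Three states: *alive without complication*, *alive post-complication*
(absorbing among the alive states), *dead* (absorbing). Annual cycles from
age 65 to age 100. The pooled 1-year complication probability
`1 - prod(1 - p_i)` over the six events is carried forward unchanged; newly
incident complication mass accrues an expected inpatient admission cost
(probability-weighted mean, weights `p_i / sum p_j`), complication-state
occupancy accrues the analogous expected chronic outpatient cost, and every
alive member accrues outpatient follow-up (plus non-medical follow-up costs
under the societal perspective).

Four structural choices are not uniquely determined by the published
descriptions of this model family; the package fixes them as follows (each
remains configurable in `ModelConfig`):

1. **Mortality composition** (`long_term_mortality="combined"`): from cycle 2
   on, the cycle death probability is
   `1 - (1 - q_trial_1y)(1 - q_ASMR(age))` — the pooled 1-year trial
   mortality is carried forward for life on top of age-specific background
   mortality. Alternatives: `asmr_only`, `max`.
2. **Life-table granularity**: age-specific mortality is consumed as
   *abridged-table* five-year death probabilities applied to each single year
   of age within the group, the form in which national schedules are
   commonly published.
3. **Accrual** (`accrual="start"`): person-time, QALYs and per-cycle costs
   use start-of-cycle occupancy. `end` and `half` (half-cycle correction)
   are available.
4. **Utility timing** (`utility_timing="u30d_first_cycle"`): the 30-day
   utility applies to the first Markov year (the year between the two
   utility measurements), the 1-year utility thereafter.

This combination reproduces the published base-case discounted life-years
and QALYs of the reference analysis to well within 3% in all three strata
and both perspectives.

### Discounting, comparison, currency

Costs and health outcomes are discounted at 3%/3% (base case) by
`1/(1+r)^cycle`; a scenario re-runs the model at 6.2% for costs and 1.3% for
health. Incremental results report an ICER only in the trade-off quadrants;
strict dominance yields the label `dominant`/`dominated` (negative ratios
are not interpretable). Net monetary benefit `wtp * dQALY - dCost` is used
wherever a quadrant-safe scalar is needed. THB amounts convert to USD by the
purchasing-power parity factor 11.72 with half-up integer rounding.

## Parameters (`avrcea.params`)

All inputs live in `src/avrcea/data/parameters.csv`
(`arm,stratum,name,mean,low,high,dist,units`): tree probabilities per
stratum (overall / isolated / with concomitant surgery), pooled 1-year
outcome probabilities, eleven admission cost components per arm, e-Claim
complication costs (inpatient and outpatient, shared by both arms),
outpatient follow-up cost, non-medical costs, and the 30-day / 1-year
utilities. Ranges are as printed in the source tables; stated-exact values
(the isolated-stratum death-after-complication probability of 0, the SUAVR
accommodation cost of 0) carry `dist=fixed` and are never varied.

## Evidence synthesis (`avrcea.meta`)

Per-study log relative risks use the delta-method standard error
`sqrt(1/e_t - 1/n_t + 1/e_c - 1/n_c)`; if any event cell is zero, 0.5 is
added to all four cells. Pooling is DerSimonian–Laird: fixed-effect weights
give Cochran's Q, `tau^2 = max(0, (Q - (k-1)) / (S1 - S2/S1))`, and
random-effects weights `1/(se^2 + tau^2)` give the pooled estimate and
normal-theory 95% CI. Pooled RRs apply multiplicatively to baseline
probabilities, clamped at 1.

## Uncertainty (`avrcea.uncertainty`)

**One-way (tornado).** Each parameter is varied individually over its
printed range; where no range exists, probabilities/utilities move ±10%
(clamped to [0, 1]) and costs ±20%; stated-exact parameters are not varied.
Both discount rates additionally sweep [0, 6%]. The outcome is the
incremental NMB at the configured willingness-to-pay (the base case sits in
a dominance quadrant, so the ICER is undefined); entries sort by descending
spread.

**Probabilistic.** Standard errors derive from printed ranges via
`(high - low)/3.92` (range treated as a 95% CI; configurable). Probabilities
and utilities draw from moment-matched beta distributions
(`nu = m(1-m)/s^2 - 1`), costs from gamma (`shape = (m/se)^2`,
`scale = se^2/m`). Shared e-Claim costs are drawn once per iteration and
applied to both arms; draws follow a fixed canonical slot order from
`numpy.random.default_rng(seed)`, making runs bit-reproducible.
Outputs: cost-effectiveness-plane samples, quadrant proportions (boundary
deltas count to the positive side; the upper-left quadrant is
`dQALY < 0, dCost >= 0`), and a two-strategy acceptability curve
(`p_ce = P(wtp * dQALY - dCost >= 0)`).

## Synthetic data (`avrcea.synth`)

Generators with known ground truth, all seeded:

* **Life tables** from a Gompertz–Makeham hazard
  `h(x) = c + a e^{bx}`, optionally grouped into 5-year death probabilities.
  The packaged `thai_life_table_synthetic.csv` is the deterministic output of
  `gen_life_table(THAI_LIKE_SPEC)` (`a = 3.34e-5`, `b = 0.090`, `c = 0.002`),
  calibrated to Thai demography (annual `q(65) ≈ 0.0135`, life expectancy at
  65 ≈ 19.5 years). It is a synthetic stand-in for the national schedule,
  not a transcription of it.
* **Cohorts** with the seven matching covariates, logistic treatment
  assignment (intercept solved by root-finding so the expected treated
  fraction matches), gamma-distributed observed valve costs and
  beta-distributed utilities.
* **Greedy 1:1 propensity matching** without replacement: unpenalized
  scikit-learn logistic scores; treated processed in descending score, each
  taking the unused control with the smallest absolute score difference
  (ties toward the lower control id). Balance is summarised by absolute
  standardized mean differences with the pooled SD always taken from the
  full cohort.
* **Meta-analysis study sets** under a random-effects RR model
  (`log RR ~ Normal(log rr, tau^2)`, binomial counts, lognormal arm sizes;
  treated risks above 1 are capped at 0.99 with a warning).

## Verification

The test suite pins the engines to independent oracles: explicit branch
enumeration for the tree, exhaustive path enumeration for 3-cycle Markov
totals (all accrual conventions and both perspectives), the geometric closed
form `(1-q)/q` for constant-hazard life-years, a brute-force
DerSimonian–Laird implementation on random inputs, CI-coverage and
`tau^2`-recovery simulations, 1e-12 moment-matching round-trips, and a
brute-force matching oracle on small cohorts. Problem sizes (1,000 PSA
draws, 1,000 coverage replicates, 4,000-draw mean checks) were chosen to
keep the whole suite under half a minute on one CPU.

## Limitations

* The bundled life table is synthetic; absolute life-year totals therefore
  track the reference analysis rather than official national statistics.
* The post-complication state is absorbing among the alive and carries a
  single pooled expected cost; complication-specific pathways are not
  modelled.
* The carried-forward 1-year trial mortality and complication probabilities
  assume the first-year risk profile persists for life.
* PSA draws parameters independently (apart from arm-shared costs); no
  correlation structure between probabilities and costs is imposed.
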