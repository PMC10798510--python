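# avrcea

Cost-utility analysis of sutureless / rapid-deployment aortic valve
replacement (SUAVR) versus conventional surgical replacement (CAVR) in
severe aortic stenosis, from the Thai health-system setting (2022 THB,
purchasing-power-parity 11.72 THB/USD, willingness-to-pay 160,000 THB/QALY).

The model is a two-part cohort simulation:

1. **30-day decision tree.** After surgery the cohort splits on early
   complication (stroke, atrial fibrillation, major bleeding, acute kidney
   injury, permanent pacemaker, paravalvular leakage, pooled into one branch)
   and on death conditional on that branch. Admission costs — and, under the
   societal perspective, direct non-medical costs — accrue at time zero.
2. **Lifetime Markov model.** Survivors enter a three-state annual-cycle
   cohort model (*alive without complication*, *alive post-complication*,
   *dead*) run from age 65 to 100. The first cycle applies the pooled 1-year
   trial mortality; later cycles fold that carried-forward trial mortality
   into age-specific background mortality from a life table. Costs and
   utilities accrue per cycle and are discounted at 3% (base case).

Around the engine the package provides DerSimonian–Laird random-effects
relative-risk pooling, one-way (tornado) and probabilistic sensitivity
analysis with beta/gamma moment matching, cost-effectiveness acceptability
curves, differential-discounting scenarios, greedy 1:1 propensity-score
matching, and seeded synthetic-data generators for every input class.

## Worked example

```python
from avrcea import base_case, load_parameters, thb_to_usd

bundle = load_parameters()        # packaged tables, config, life table
trt, ctl, cmp = base_case(bundle, stratum="overall", perspective="societal")

print(trt.total_cost, thb_to_usd(trt.total_cost))  # SUAVR lifetime cost
print(ctl.ly, ctl.qaly)                            # CAVR ~6.3 LY, ~5.1 QALY
print(trt.ly, trt.qaly)                            # SUAVR ~6.2 LY, ~5.0 QALY
print(cmp.classification)                          # "dominated"
```

SUAVR costs more (driven almost entirely by the valve price: 458,818 vs
137,186 THB, a 321,632 THB ≈ 27,443 USD difference) and yields slightly fewer
QALYs, so it is dominated by CAVR in the base case — in both perspectives and
in all three strata (overall, isolated AVR, AVR with concomitant surgery).
Probabilistic analysis concentrates about 79% of draws in the upper-left
cost-effectiveness-plane quadrant, and the acceptability curve favours CAVR at
every willingness-to-pay up to 400,000 THB/QALY. The one-way tornado is led
by the SUAVR valve cost and the 1-year utilities, with long-term mortality
the most influential transition probability.

## Command line

```bash
avrcea base      --out out/base            # totals, ICER/dominance table
avrcea dsa       --out out/dsa             # tornado of incremental NMB
avrcea psa       --out out/psa --seed 20220 --iterations 1000
avrcea scenario  --out out/scen            # 6.2% cost / 1.3% health discounting
avrcea simulate  --out out/sim --seed 1    # synthetic datasets
```

Every command writes CSV outputs plus a `manifest.json` with the seed, the
config hash, and the package version; identical seeds reproduce outputs
byte-for-byte.

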