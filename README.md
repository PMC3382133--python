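# afibcea

Markov cohort cost-effectiveness model of anticoagulation strategies for
stroke prevention in atrial fibrillation. The package compares four
lifelong strategies in a cohort of 65-year-old patients with newly
diagnosed AF and CHADS₂ ≥ 2, from the healthcare-payer perspective:

1. usual warfarin anticoagulation care (mean TTR 64%),
2. genotype-guided warfarin care (CYP2C9/VKORC1-informed dosing with
   intensified monitoring; assumed TTR 78.9%),
3. dabigatran 110 mg twice daily,
4. dabigatran 150 mg twice daily.

It is written for health-economics researchers and methodologists who
want a fully scripted, testable implementation of this class of decision
model: a deterministic monthly-cycle cohort engine over health-state ×
therapy pairs, TTR-partitioned warfarin event rates, discounted cost and
QALY accumulation, dominance/ICER analysis, one-way and two-way
deterministic sensitivity analysis with threshold search, and a
probabilistic sensitivity analysis with cost-effectiveness acceptability
curves.

## The model in brief

Warfarin arms derive effective annual event rates from time in
therapeutic range (TTR):

```
r_eff = r_in · [TTR + f_below·(1−TTR)·RR_below + (1−f_below)·(1−TTR)·RR_above]
```

with stroke risk elevated below range and bleeding risk above range.
Dabigatran rates apply trial relative risks to the usual-care rates.
Monthly transition probabilities use a constant-hazard conversion
`p = 1 − exp(−r/12)`. Survivors of major bleeding switch to aspirin;
stroke survivors switch to dabigatran 150 mg (aspirin if they have a
bleeding history). Costs and QALYs are discounted at 3%/year over a
25-year horizon; strategies are ranked by dominance and incremental
cost-effectiveness ratios (ICER = Δcost/ΔQALY), with 50,000 USD/QALY as
the willingness-to-pay threshold. Background mortality comes from a
packaged synthetic life table whose hazard multiplier is calibrated so
the usual-care arm reproduces the published lifetime QALY total; see
`docs/methods.md` for the full specification.

## Worked example

```python
from afibcea import load_parameters, run_all_strategies, accumulate, build_cea_table

ps = load_parameters()                      # packaged base case
traces = run_all_strategies(ps)
results = [accumulate(tr, ps) for tr in traces.values()]
print(build_cea_table(results, ps.config.wtp_threshold))
```

prints (costs in USD, rounded; QALYs discounted):

```
      strategy   cost  qalys    status   dominated_by  comparator   icer
   genotype_ac  84581  9.544  frontier
      usual_ac  89661  9.444 dominated    genotype_ac
dabigatran_150  91796 10.042  frontier                genotype_ac 14,479
dabigatran_110 102030  9.993 dominated dabigatran_150
```

Usual care is dominated by genotype-guided care (costlier, fewer QALYs)
and dabigatran 110 mg by 150 mg; dabigatran 150 mg buys its extra 0.50
QALYs over genotype-guided care at 14,479 USD each, below the 50,000
USD/QALY threshold, so it is the preferred strategy at base case. The
same analyses are available from a CLI:

```
afibcea run --out-dir out          # cost-effectiveness table
afibcea events                     # per-therapy event-rate diagnostics
afibcea validate                   # simulated vs trial event rates
afibcea owsa --param inr.ttr_genotype
afibcea twsa --params utilities.u_warfarin,utilities.u_dabigatran
afibcea psa --n 10000 --seed 42
afibcea calibrate --target 9.444
```

Every run writes CSV/JSON outputs plus a manifest (input digest, seed,
version) sufficient to reproduce it.

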