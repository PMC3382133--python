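# Methods

## Decision problem and model structure

`afibcea` evaluates four lifelong anticoagulation strategies for a
cohort of 65-year-old patients with newly diagnosed atrial fibrillation
at elevated stroke risk (CHADS₂ ≥ 2): usual warfarin anticoagulation
care (mean TTR 64%), genotype-guided warfarin care (CYP2C9/VKORC1-informed
dosing plus intensified monitoring for genotype-sensitive patients,
assumed TTR 78.9%), and dabigatran 110 mg or 150 mg twice daily.

The engine is a deterministic Markov cohort model with monthly cycles
over a 25-year horizon (300 cycles). The state space is the product of a
health dimension — well, dyspepsia, post-MI, ischemic stroke with major,
minor or no residual deficit, post-ICH, a combined ICH-plus-stroke
state, dead — and a current-therapy dimension (the two warfarin
variants, the two dabigatran doses, aspirin). All four strategies share
one transition structure and differ only in the initial therapy, so one
set of transition matrices serves all arms of a run.

### Event model

Warfarin event rates are partitioned by INR control. With a fraction
`TTR` of patient-time in the 2–3 target range and a fraction `f_below`
of out-of-range time spent below range, the effective annual rate is

    r_eff = r_in · [TTR + f_below·(1−TTR)·RR_below + (1−f_below)·(1−TTR)·RR_above]

Stroke risk is elevated below range (RR 1.70) and unchanged above;
major-bleeding risk is elevated above range (RR 8.28) and unchanged
below. With the base-case inputs this gives 3.39 major bleeds and 1.47
ischemic strokes per 100 patient-years in usual care. Dabigatran rates
apply the RE-LY relative risks to the usual-care rates; aspirin (the
post-bleed fallback) has its own stroke rate and a relative-risk-scaled
bleeding rate, both anchored to usual care. MI rates are
therapy-specific absolute rates with no INR dependence.

Annual rates convert to monthly probabilities by constant hazard,
`p = 1 − exp(−r/12)`, rather than division by 12, so probabilities stay
bounded for the extreme relative-risk draws of the probabilistic
analysis; at base-case magnitudes the two conversions differ in the
fourth decimal.

### Within-cycle event resolution

Competing monthly events follow a fixed precedence — background death,
ICH, ECH, ischemic stroke, MI, dyspepsia onset — with multiplicative
survival of earlier events, which conserves cohort mass exactly and
makes joint-occurrence corrections O(10⁻⁵) at monthly probabilities.

Consequence rules:

- **Major bleeds** split into intracranial/extracranial by a
  therapy-specific ICH fraction. Survivors stop anticoagulation and
  continue on aspirin alone. ICH survivors move to post-ICH (or to the
  combined state if they already have a residual-deficit stroke); ECH
  survivors return to their prior health state, with the acute ECH
  utility (0.80) applied for the event cycle only.
- **Ischemic-stroke** survivors switch to dabigatran 150 mg (including
  escalation from 110 mg; a no-op for patients already on 150 mg),
  except patients with a bleeding history (post-ICH), who stay on
  aspirin and enter the combined ICH-plus-stroke state.
- A new permanent sequela replaces the current health state only when
  its utility is no higher (utility-floor semantics): a major-deficit
  stroke overwrites a minor one, never vice versa.
- **MI** survivors enter the permanent post-MI state (utility 0.84, no
  ongoing monthly cost — none is published) retaining their therapy.
- **Dyspepsia** is a permanent utility-modifier state entered from
  "well" on dabigatran only; its onset rate is unpublished and defaults
  to zero (opt-in).
- "No residual deficit" strokes are well-equivalent for utility and
  ongoing cost but incur the TIA-level one-time cost.

### Background mortality and calibration

The published inputs contain no background-mortality table, yet the
lifetime QALY totals imply substantial non-event mortality. The package
ships a *synthetic* Gompertz-shaped life table (annual death probability
0.013 at 65, hazard doubling ≈ 7.2 years) with a scalar hazard
multiplier. `calibrate_mortality` bisects the multiplier until the
usual-care arm's discounted QALYs equal the published base-case total
(9.444); the packaged configuration bakes in the result (1.7303). The
usual-care arm is the calibration target because it has the fewest
interpretive gaps; every other arm is then a fixed prediction. With the
calibrated table the model reproduces the published base case closely:
genotype-guided care 84,581 USD / 9.544 QALYs (published 85,627 /
9.554), dabigatran 150 mg 91,796 / 10.042 (92,684 / 10.065), both
dominance relations, and an ICER of 14,479 USD/QALY for dabigatran
150 mg vs genotype-guided care (published 13,810).

The tabulated annual probability is treated as a hazard when scaled:
`p_month = 1 − exp(−m·q_annual/12)`, so a multiplier of 2 doubles the
hazard, not the probability.

## Economics

- **QALYs**: monthly accrual from end-of-cycle occupancy; a state's
  utility is therapy utility × worst-sequela utility (product by
  default; `minimum` available via `config.utility_combination`).
  Dead = 0. The aspirin therapy utility is unpublished and defaults to
  1.0 by the same no-monitoring-burden reasoning applied to dabigatran.
  The combined ICH-plus-stroke sequela utility is min(u_ICH,
  u_stroke_major).
- **Costs**: monthly drug plus monitoring cost by current therapy
  (usual care 31 + 6 USD; genotype arm monitoring weighted by the 29.2%
  prevalence of normal-sensitivity genotypes,
  31·[0.292 + 0.708·2] = 52.95 USD/month, plus a one-time 72 USD
  genotyping cost; dabigatran 240 USD with no routine monitoring;
  aspirin 0 by default), chronic state costs (ICH 5,740; major stroke
  5,430; minor stroke 2,500; combined 7,280 USD/month), and one-time
  event costs at incidence. Fatal strokes are costed at the
  moderate-to-severe level; fatal bleeds carry the full event cost; MI
  uses separate survived/dead one-time costs.
- **Discounting**: 3%/year for both costs and QALYs, applied from cycle
  start (`(1+r)^(−k/12)` for cycle k); no half-cycle correction by
  default (a flag exists).

Dominance analysis removes strongly dominated strategies (more costly,
fewer QALYs), flags extended dominance separately (the published
analysis uses only strong dominance), and reports Δcost/ΔQALY ICERs
along the frontier. The preferred strategy at a willingness-to-pay
threshold (50,000 USD/QALY) is the most effective frontier strategy
with ICER at or below it, which provably agrees with maximizing net
monetary benefit.

## Sensitivity analysis

One-way analysis re-runs the model across a parameter's declared range
(25 points by default) and reports the dabigatran-150-vs-genotype ICER,
with ±∞ sentinels when one strategy dominates (never interpolated).
Threshold search scans for sign changes of ICER − target and bisects to
within 1 USD/QALY, returning all crossings with a warning if the ICER is
non-monotone. Two-way analysis labels each cell of a parameter-pair grid
(41×41 by default) with the strategy of maximal net monetary benefit.
At the base case the model reproduces the published qualitative
findings: the ICER crosses 50,000 USD/QALY at genotype-arm TTR ≈ 0.98,
at warfarin utility ≈ 0.99, and when dabigatran utility falls to 0.95;
genotype-guided care is preferred whenever warfarin's utility is at
least dabigatran's.

## Probabilistic sensitivity analysis

The PSA is the package's synthetic-data stage: every ranged parameter is
drawn independently and uniformly over its declared bounds — the only
distribution implied by published ranges alone (a scaled Beta(2,2)
option exists for robustness checks). Severity distributions are
renormalized after drawing. Each iteration re-runs all four strategies;
acceptability curves report the probability of maximal net monetary
benefit over a 0–150,000 USD/QALY grid, with ties split equally, and
paired per-iteration differences give mean Δcost/ΔQALY with percentile
intervals. Draws are reproducible bit-for-bit from the seed.

A structural consequence of uniform-over-range sampling deserves
emphasis: several published ranges are strongly one-sided around their
base values (stroke RR below range: base 1.70, range 1.70–6.88; in-range
bleeding rate and above-range bleeding RR both at their range tops). At
the range midpoints the genotype and dabigatran-150 arms have nearly
equal stroke rates, and the two therapy-utility draws share the same
uniform [0.95, 1.0] distribution, so the expected paired QALY difference
between dabigatran 150 mg and genotype-guided care is approximately
zero and the acceptability split at 50,000 USD/QALY tilts toward
genotype-guided care (≈ 0.78 vs 0.20 at n = 2,000) rather than the
near-even split reported for the original analysis. A published mean
QALY gain of ~0.2 with symmetric utility draws is not arithmetically
reachable under uniform-over-range sampling of the stroke inputs, which
indicates the original Monte Carlo used base-centred distributions that
were not described. The package reports what uniform sampling actually
yields rather than adopting undocumented distributions.

## What the generator does and does not emulate

The PSA sampler and the deterministic engine together emulate parameter
uncertainty exactly as declared in the published ranges, under
independence. They do not emulate: correlation between inputs (none is
published), age-dependent event-rate escalation, INR trajectories or
dose titration within the TTR summary, individual-level heterogeneity
(a micro-simulation exists only as a test oracle), or calendar-time
drug-price changes. Passing tests therefore demonstrate fidelity to the
published decision model, not forecasts for any real cohort.

## Numerical choices

- Mass conservation enforced to 1e-9 per cycle; negative mass to
  −1e-12.
- Severity distributions renormalized at load when their printed sum is
  within 0.005 of 1 (the aspirin set prints 0.999); larger deviations
  are errors. Declared ranges are widened minimally (≈2e-4) to contain
  renormalized base values.
- Calibration bisection: multiplier bracket [0, 10], QALY tolerance
  0.005; threshold bisection: 1 USD/QALY.
- Event rates per 100 patient-years use end-of-cycle alive person-time;
  the headline validation rate restricts events and person-time to the
  arm's initial therapy (undiluted by post-event switches), with the
  intention-to-treat variant reported alongside.
- Problem sizes in the shipped tests and examples: 300-cycle horizon
  (the full published horizon), 2,000 PSA iterations, 10⁶-path one-cycle
  micro-simulation oracle, 25-point one-way and up to 41×41 two-way
  grids.

## Known limitations

- Background mortality is a synthetic calibrated table, not a published
  life table; absolute cost/QALY levels inherit its shape, though the
  calibration pins the usual-care QALY total and the *incremental*
  comparisons are insensitive to modest shape changes.
- The analytic usual-care stroke rate implied by the TTR partition
  (1.47/100 pt-yr) exceeds the cohort-level value the original analysis
  reports (1.35); nothing in the published inputs produces the gap, and
  the validation report quantifies it rather than hiding it.
- Dyspepsia incidence, aspirin drug cost, and aspirin therapy utility
  are unpublished; they default to 0, 0, and 1.0 respectively and are
  configurable.
- Therapy-switch rules for edge cases (escalation of 110 mg stroke
  survivors to 150 mg; aspirin retention after stroke in post-ICH
  patients) follow the single published switching sentence plus a
  bleeding-history contraindication reading; both are flagged
  interpretive.
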