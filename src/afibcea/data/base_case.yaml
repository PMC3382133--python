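# Base-case model inputs with deterministic/probabilistic sensitivity ranges.
# Rates are annual (per patient-year, as fractions); costs are USD.
# A leaf of the form {value: x, range: [lo, hi]} declares a ranged parameter;
# plain scalars are fixed.

inr:
  ttr_usual: {value: 0.64, range: [0.57, 0.655]}
  ttr_genotype: {value: 0.789, range: [0.65, 1.0]}
  frac_below_of_out: {value: 0.52, range: [0.42, 0.62]}
  prev_normal_sensitivity: {value: 0.292, range: [0.234, 0.350]}

events:
  stroke_rate_in_range: {value: 0.013, range: [0.005, 0.016]}
  rr_stroke_below: {value: 1.70, range: [1.70, 6.88]}
  rr_stroke_above: 1.0          # assumed equal to in-range risk
  bleed_rate_in_range: {value: 0.015, range: [0.010, 0.015]}
  rr_bleed_above: {value: 8.28, range: [3.21, 8.28]}
  rr_bleed_below: 1.0           # assumed equal to in-range risk
  stroke_rate_aspirin: {value: 0.027, range: [0.008, 0.137]}
  rr_bleed_aspirin_vs_warfarin: {value: 0.64, range: [0.50, 0.80]}
  rr_stroke_d150: {value: 0.76, range: [0.59, 0.97]}
  rr_stroke_d110: {value: 1.11, range: [0.88, 1.39]}
  rr_bleed_d150: {value: 0.93, range: [0.81, 1.07]}
  rr_bleed_d110: {value: 0.80, range: [0.70, 0.93]}
  mi_rate_warfarin: {value: 0.0064, range: [0.0051, 0.0077]}
  mi_rate_aspirin: {value: 0.0053, range: [0.0040, 0.0060]}
  mi_rate_d150: {value: 0.0081, range: [0.0065, 0.0097]}
  mi_rate_d110: {value: 0.0082, range: [0.0066, 0.0098]}
  # No published onset incidence for dyspepsia; opt-in per therapy.
  dyspepsia_rate_by_therapy:
    warfarin_usual: 0.0
    warfarin_genotype: 0.0
    dabigatran_150: 0.0
    dabigatran_110: 0.0
    aspirin: 0.0

outcomes:
  stroke_severity_anticoag:       # warfarin or dabigatran
    fatal: {value: 0.082, range: [0.082, 0.101]}
    major: {value: 0.402, range: [0.402, 0.417]}
    minor: {value: 0.425, range: [0.348, 0.425]}
    none: {value: 0.091, range: [0.090, 0.133]}
  stroke_severity_aspirin:        # sums to 0.999 as published; renormalized at load
    fatal: {value: 0.179, range: [0.101, 0.179]}
    major: {value: 0.30, range: [0.30, 0.417]}
    minor: {value: 0.41, range: [0.348, 0.41]}
    none: {value: 0.11, range: [0.11, 0.133]}
  ich_fraction_by_therapy:        # proportion of major bleeds that are intracranial
    warfarin: {value: 0.22, range: [0.18, 0.25]}
    dabigatran_150: {value: 0.126, range: [0.063, 0.134]}
    dabigatran_110: {value: 0.089, range: [0.046, 0.119]}
    aspirin: {value: 0.21, range: [0.16, 0.25]}
  ich_mortality: {value: 0.486, range: [0.36, 0.61]}
  ech_mortality: {value: 0.051, range: [0.001, 0.101]}
  mi_mortality: {value: 0.15, range: [0.103, 0.246]}

utilities:
  u_warfarin: {value: 0.95, range: [0.95, 1.0]}
  u_dabigatran: {value: 1.0, range: [0.95, 1.0]}
  u_aspirin: 1.0                  # not published; same no-monitoring reasoning as dabigatran
  u_ich: {value: 0.51, range: [0.15, 0.85]}
  u_ech: {value: 0.80, range: [0.79, 0.84]}
  u_stroke_major: {value: 0.39, range: [0.0, 0.50]}
  u_stroke_minor: {value: 0.75, range: [0.50, 0.99]}
  u_mi: {value: 0.84, range: [0.67, 0.96]}
  u_dyspepsia: {value: 0.97, range: [0.74, 0.98]}
  u_dead: 0.0

costs:
  genotyping_once: {value: 72, range: [50, 200]}
  ac_monthly: {value: 31, range: [21, 36]}
  intensified_multiplier: {value: 2, range: [2, 3]}
  warfarin_monthly: {value: 6, range: [4, 20]}
  dabigatran_monthly: {value: 240, range: [200, 270]}   # both doses
  aspirin_monthly: 0.0            # not published; opt-in
  dabigatran_monitoring_monthly: 0.0
  onetime_ich: {value: 45959, range: [21675, 55151]}
  onetime_ech: {value: 23798, range: [17445, 39308]}
  onetime_stroke_major: {value: 65984, range: [53243, 78724]}
  onetime_stroke_minor: {value: 44043, range: [35234, 52852]}
  onetime_stroke_none: {value: 19514, range: [15611, 23417]}   # TIA-level stay
  onetime_mi_survived: {value: 27996, range: [20945, 43727]}
  onetime_mi_dead: {value: 20654, range: [14447, 44498]}
  monthly_ich: {value: 5740, range: [2100, 10000]}
  monthly_stroke_major: {value: 5430, range: [2100, 9000]}
  monthly_stroke_minor: {value: 2500, range: [1000, 4300]}
  monthly_ich_and_stroke: {value: 7280, range: [3180, 13790]}

config:
  start_age: 65
  horizon_cycles: 300
  cycle_length_months: 1
  discount_rate_annual: 0.03
  wtp_threshold: 50000
  half_cycle_correction: false
  # Background-mortality hazard multiplier on the packaged life table,
  # calibrated so the usual-care arm's discounted lifetime QALYs equal the
  # published base-case total (see afibcea.validation.calibrate_mortality).
  mortality_multiplier: 1.7303
  utility_combination: product
  psa_distribution: uniform
  rng_seed: 0
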