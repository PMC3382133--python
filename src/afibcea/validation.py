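"""Model validation against trial event rates and mortality calibration.

Validation compares cohort-simulated major-bleeding and ischemic-stroke
rates (per 100 patient-years) with the rates reported for the
corresponding arms of the RE-LY anticoagulation trial.  The headline
simulated rate attributes events and person-time to the arm's *initial*
therapy (so the therapy-specific rate is not diluted by post-event
switches to aspirin or dabigatran); the intention-to-treat variant over
all alive person-time is reported alongside, since either denominator is
defensible.

Background mortality is not an event-rate input of the model; the
packaged life table carries a scalar hazard multiplier calibrated by
bisection so the usual-care arm's discounted lifetime QALYs match the
published base-case total.  All other arms are then fixed predictions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Tuple

import pandas as pd

from .economics import accumulate
from .markov import CohortTrace, run_all_strategies
from .parameters import ParameterSet

__all__ = [
    "TRIAL_REFERENCE_RATES",
    "ValidationReport",
    "simulated_event_rates",
    "validate_against_rely",
    "calibrate_mortality",
]

#: RE-LY arm event rates per 100 patient-years (bleed = major bleeding,
#: stroke = ischemic stroke); the warfarin arm anchors both warfarin
#: strategies of the model.
TRIAL_REFERENCE_RATES: Dict[str, Dict[str, float]] = {
    "usual_ac": {"bleed": 3.57, "stroke": 1.20},
    "genotype_ac": {"bleed": 3.57, "stroke": 1.20},
    "dabigatran_110": {"bleed": 2.87, "stroke": 1.34},
    "dabigatran_150": {"bleed": 3.32, "stroke": 0.92},
}


def simulated_event_rates(trace: CohortTrace, denominator: str = "on_initial") -> Dict[str, float]:
    """Cumulative event rates per 100 patient-years from a cohort trace.

    ``denominator='on_initial'`` restricts events and person-time to the
    arm's initial therapy; ``'all'`` uses every incident event over all
    alive person-time (intention-to-treat).
    """
    if denominator == "on_initial":
        pt = float(trace.person_time_on_initial.sum())
        if pt <= 0:
            raise ValueError("zero person-time on initial therapy")
        ev = trace.events_on_initial
        return {
            "stroke": float(ev["stroke"].sum()) / pt * 100.0,
            "bleed": float(ev["bleed"].sum()) / pt * 100.0,
        }
    if denominator == "all":
        pt = float(trace.person_time.sum())
        if pt <= 0:
            raise ValueError("zero person-time")
        ev = trace.events
        return {
            "stroke": float(ev["stroke"].sum()) / pt * 100.0,
            "bleed": float((ev["ich"] + ev["ech"]).sum()) / pt * 100.0,
        }
    raise ValueError(f"unknown denominator {denominator!r}")


@dataclass
class ValidationReport:
    table: pd.DataFrame

    def __str__(self) -> str:
        return self.table.round(3).to_string(index=False)


def validate_against_rely(ps: ParameterSet) -> ValidationReport:
    """Simulated vs trial-reported event rates for all four strategies."""
    traces = run_all_strategies(ps)
    rows = []
    for s, trace in traces.items():
        sim = simulated_event_rates(trace, "on_initial")
        sim_itt = simulated_event_rates(trace, "all")
        ref = TRIAL_REFERENCE_RATES[s]
        for event in ("bleed", "stroke"):
            rows.append({
                "strategy": s,
                "event": event,
                "simulated": sim[event],
                "simulated_itt": sim_itt[event],
                "reference": ref[event],
                "abs_deviation": sim[event] - ref[event],
                "rel_deviation": (sim[event] - ref[event]) / ref[event],
            })
    return ValidationReport(table=pd.DataFrame(rows))


def _usual_qalys(ps: ParameterSet, multiplier: float, strategy: str) -> float:
    trial = ps.copy_deep()
    trial.config.mortality_multiplier = multiplier
    traces = run_all_strategies(trial, [strategy])
    return accumulate(traces[strategy], trial).discounted_qalys


def calibrate_mortality(
    ps: ParameterSet,
    target_qalys: float,
    strategy: str = "usual_ac",
    bracket: Tuple[float, float] = (0.0, 10.0),
    tol: float = 0.005,
) -> Tuple[float, float]:
    """Bisect the background-mortality multiplier to hit a QALY target.

    Discounted QALYs are monotone decreasing in the multiplier.  Returns
    ``(multiplier, achieved_qalys)``; raises if the target lies outside
    what the bracket can reach.
    """
    lo, hi = bracket
    q_lo = _usual_qalys(ps, lo, strategy)  # highest achievable QALYs
    q_hi = _usual_qalys(ps, hi, strategy)
    if abs(q_lo - target_qalys) < tol:
        return lo, q_lo
    if abs(q_hi - target_qalys) < tol:
        return hi, q_hi
    if not (q_hi < target_qalys < q_lo):
        raise ValueError(
            f"target {target_qalys} QALYs outside achievable bracket "
            f"[{q_hi:.3f}, {q_lo:.3f}] for multiplier in [{lo}, {hi}]"
        )
    for _ in range(100):
        mid = 0.5 * (lo + hi)
        q_mid = _usual_qalys(ps, mid, strategy)
        if abs(q_mid - target_qalys) < tol:
            return mid, q_mid
        if q_mid > target_qalys:
            lo = mid
        else:
            hi = mid
    return mid, q_mid
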