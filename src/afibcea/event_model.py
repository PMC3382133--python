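"""Effective per-cycle event probabilities for each therapy.

Warfarin event rates are built by partitioning patient-time by INR
control: a fraction TTR of time is spent in the therapeutic range at the
in-range event rate, and out-of-range time is split into below-range and
above-range shares carrying their respective relative risks.  Ischemic
stroke risk is elevated below range; major-bleeding risk is elevated
above range (the opposite off-range risks are assumed equal to
in-range).  Dabigatran rates apply trial relative risks to the
usual-care warfarin rates; aspirin (the post-bleed fallback therapy) has
its own stroke rate and a relative-risk-scaled bleeding rate.
Myocardial-infarction rates are therapy-specific absolute rates with no
INR dependence.

Annual rates are converted to monthly probabilities under a
constant-hazard assumption, which keeps probabilities bounded for the
extreme relative-risk draws of the probabilistic sensitivity analysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict

from .parameters import ParameterSet, SeverityDistribution, THERAPIES

__all__ = [
    "TherapyEventProfile",
    "partition_annual_rate",
    "annual_rate_to_monthly_prob",
    "apply_relative_risk",
    "build_event_profiles",
]


def partition_annual_rate(
    rate_in_range: float,
    rr_below: float,
    rr_above: float,
    ttr: float,
    frac_below: float,
) -> float:
    """Time-weighted annual event rate over the INR-control partition.

    ``rate_in_range * [ttr + frac_below*(1-ttr)*rr_below
    + (1-frac_below)*(1-ttr)*rr_above]``.
    """
    if rate_in_range < 0 or rr_below < 0 or rr_above < 0:
        raise ValueError("rates and relative risks must be non-negative")
    if not (0.0 <= ttr <= 1.0 and 0.0 <= frac_below <= 1.0):
        raise ValueError("ttr and frac_below must lie in [0, 1]")
    out = 1.0 - ttr
    return rate_in_range * (ttr + frac_below * out * rr_below + (1.0 - frac_below) * out * rr_above)


def annual_rate_to_monthly_prob(rate: float) -> float:
    """Constant-hazard conversion ``1 - exp(-rate/12)``."""
    if rate < 0:
        raise ValueError(f"annual rate must be >= 0, got {rate}")
    return -math.expm1(-rate / 12.0)


def apply_relative_risk(base_rate: float, rr: float) -> float:
    """Scale an annual rate by a relative risk."""
    if base_rate < 0:
        raise ValueError(f"base rate must be >= 0, got {base_rate}")
    if rr <= 0:
        raise ValueError(f"relative risk must be > 0, got {rr}")
    return base_rate * rr


@dataclass(frozen=True)
class TherapyEventProfile:
    """Per-therapy monthly event probabilities and event-outcome inputs."""

    therapy: str
    annual_stroke: float
    annual_major_bleed: float
    annual_mi: float
    annual_dyspepsia_onset: float
    monthly_p_stroke: float
    monthly_p_major_bleed: float
    monthly_p_mi: float
    monthly_p_dyspepsia_onset: float
    ich_fraction: float
    severity: SeverityDistribution


def _profile(
    therapy: str,
    stroke: float,
    bleed: float,
    mi: float,
    dysp: float,
    ich_fraction: float,
    severity: SeverityDistribution,
) -> TherapyEventProfile:
    return TherapyEventProfile(
        therapy=therapy,
        annual_stroke=stroke,
        annual_major_bleed=bleed,
        annual_mi=mi,
        annual_dyspepsia_onset=dysp,
        monthly_p_stroke=annual_rate_to_monthly_prob(stroke),
        monthly_p_major_bleed=annual_rate_to_monthly_prob(bleed),
        monthly_p_mi=annual_rate_to_monthly_prob(mi),
        monthly_p_dyspepsia_onset=annual_rate_to_monthly_prob(dysp),
        ich_fraction=ich_fraction,
        severity=severity,
    )


def warfarin_annual_rates(ps: ParameterSet, ttr: float) -> Dict[str, float]:
    """Annual stroke and major-bleeding rates on warfarin at a given TTR."""
    ev = ps.events
    stroke = partition_annual_rate(
        ev.stroke_rate_in_range, ev.rr_stroke_below, ev.rr_stroke_above,
        ttr, ps.inr.frac_below_of_out,
    )
    bleed = partition_annual_rate(
        ev.bleed_rate_in_range, ev.rr_bleed_below, ev.rr_bleed_above,
        ttr, ps.inr.frac_below_of_out,
    )
    return {"stroke": stroke, "bleed": bleed}


def build_event_profiles(ps: ParameterSet) -> Dict[str, TherapyEventProfile]:
    """One :class:`TherapyEventProfile` per therapy.

    Dabigatran and aspirin bleeding rates are anchored to the *usual-care*
    warfarin rates, matching how the trial relative risks were measured.
    """
    ev = ps.events
    out = ps.outcomes
    dysp = ev.dyspepsia_rate_by_therapy
    sev_ac = out.stroke_severity_anticoag
    sev_asa = out.stroke_severity_aspirin
    ichf = out.ich_fraction_by_therapy

    usual = warfarin_annual_rates(ps, ps.inr.ttr_usual)
    genotype = warfarin_annual_rates(ps, ps.inr.ttr_genotype)

    profiles = {
        "warfarin_usual": _profile(
            "warfarin_usual", usual["stroke"], usual["bleed"],
            ev.mi_rate_warfarin, dysp.get("warfarin_usual", 0.0),
            ichf["warfarin"], sev_ac,
        ),
        "warfarin_genotype": _profile(
            "warfarin_genotype", genotype["stroke"], genotype["bleed"],
            ev.mi_rate_warfarin, dysp.get("warfarin_genotype", 0.0),
            ichf["warfarin"], sev_ac,
        ),
        "dabigatran_150": _profile(
            "dabigatran_150",
            apply_relative_risk(usual["stroke"], ev.rr_stroke_d150),
            apply_relative_risk(usual["bleed"], ev.rr_bleed_d150),
            ev.mi_rate_d150, dysp.get("dabigatran_150", 0.0),
            ichf["dabigatran_150"], sev_ac,
        ),
        "dabigatran_110": _profile(
            "dabigatran_110",
            apply_relative_risk(usual["stroke"], ev.rr_stroke_d110),
            apply_relative_risk(usual["bleed"], ev.rr_bleed_d110),
            ev.mi_rate_d110, dysp.get("dabigatran_110", 0.0),
            ichf["dabigatran_110"], sev_ac,
        ),
        "aspirin": _profile(
            "aspirin",
            ev.stroke_rate_aspirin,
            apply_relative_risk(usual["bleed"], ev.rr_bleed_aspirin_vs_warfarin),
            ev.mi_rate_aspirin, dysp.get("aspirin", 0.0),
            ichf["aspirin"], sev_asa,
        ),
    }
    assert set(profiles) == set(THERAPIES)
    return profiles
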