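"""Discounted costs, QALYs, and the cost-effectiveness table.

QALYs accrue monthly from state occupancy weighted by state utility,
where a state's utility combines the current therapy's utility with the
worst permanent sequela's utility (multiplicatively by default; a
``minimum`` combination is available).  The acute extracranial-bleed
utility replaces the state utility for the event cycle only.  Costs
accrue monthly (drug, anticoagulation monitoring, chronic state costs)
plus one-time event costs at incidence; the genotype-guided arm pays a
one-time genotyping cost and an intensified-monitoring premium weighted
by the prevalence of warfarin-sensitive genotypes.  Both costs and QALYs
are discounted annually from cycle start.

The cost-effectiveness table removes strongly dominated strategies
(more costly, fewer QALYs), flags extendedly dominated ones separately,
and reports incremental cost-effectiveness ratios along the efficiency
frontier.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .markov import CohortTrace, HEALTH_STATES, EngineTables, _sequela_utility
from .parameters import ParameterSet

__all__ = [
    "StrategyResult",
    "CEATable",
    "discount_factor",
    "accumulate",
    "build_cea_table",
    "net_monetary_benefit",
    "evaluate_strategies",
]

_CHRONIC_MONTHLY = {
    "POST_ICH": "monthly_ich",
    "STROKE_MAJOR": "monthly_stroke_major",
    "STROKE_MINOR": "monthly_stroke_minor",
    "POST_ICH_STROKE": "monthly_ich_and_stroke",
}


def discount_factor(cycle: int | np.ndarray, ps_or_rate) -> float | np.ndarray:
    """Annual discounting at monthly resolution: ``(1+r)^(-cycle/12)``."""
    r = ps_or_rate if isinstance(ps_or_rate, (int, float)) else ps_or_rate.config.discount_rate_annual
    return (1.0 + r) ** (-np.asarray(cycle, dtype=float) / 12.0)


@dataclass
class StrategyResult:
    strategy: str
    discounted_cost: float
    discounted_qalys: float
    undiscounted_qalys: float
    life_years: float
    event_rates: Dict[str, float] = field(default_factory=dict)


def _therapy_utility(ps: ParameterSet, therapy: str) -> float:
    u = ps.utilities
    if therapy.startswith("warfarin"):
        return u.u_warfarin
    if therapy.startswith("dabigatran"):
        return u.u_dabigatran
    if therapy == "aspirin":
        return u.u_aspirin
    return 0.0


def _combine(ps: ParameterSet, u_therapy: float, u_seq: float) -> float:
    if ps.config.utility_combination == "minimum":
        return min(u_therapy, u_seq)
    return u_therapy * u_seq


def _monthly_therapy_cost(ps: ParameterSet, therapy: str) -> float:
    c = ps.costs
    if therapy == "warfarin_usual":
        return c.warfarin_monthly + c.ac_monthly
    if therapy == "warfarin_genotype":
        prev = ps.inr.prev_normal_sensitivity
        monitoring = c.ac_monthly * (prev + (1.0 - prev) * c.intensified_multiplier)
        return c.warfarin_monthly + monitoring
    if therapy.startswith("dabigatran"):
        return c.dabigatran_monthly + c.dabigatran_monitoring_monthly
    if therapy == "aspirin":
        return c.aspirin_monthly
    return 0.0


def state_utility_vector(ps: ParameterSet, states) -> np.ndarray:
    useq = _sequela_utility(ps)
    return np.array([
        0.0 if h == "DEAD" else _combine(ps, _therapy_utility(ps, t), useq[h])
        for h, t in states
    ])


def state_monthly_cost_vector(ps: ParameterSet, states) -> np.ndarray:
    c = ps.costs
    out = np.zeros(len(states))
    for i, (h, t) in enumerate(states):
        if h == "DEAD":
            continue
        chronic = getattr(c, _CHRONIC_MONTHLY[h]) if h in _CHRONIC_MONTHLY else 0.0
        out[i] = _monthly_therapy_cost(ps, t) + chronic
    return out


def _event_cost_vector(ps: ParameterSet, columns: Sequence[str]) -> np.ndarray:
    c = ps.costs
    # Fatal strokes are costed at the moderate-to-severe level; incident
    # bleeds (fatal or not) carry the full one-time event cost.
    per_event = {
        "ich": c.onetime_ich,
        "ech": c.onetime_ech,
        "stroke_major": c.onetime_stroke_major,
        "stroke_minor": c.onetime_stroke_minor,
        "stroke_none": c.onetime_stroke_none,
        "stroke_fatal": c.onetime_stroke_major,
        "mi_survived": c.onetime_mi_survived,
        "mi_fatal": c.onetime_mi_dead,
    }
    return np.array([per_event.get(col, 0.0) for col in columns])


def accumulate(trace: CohortTrace, ps: ParameterSet, strategy: Optional[str] = None) -> StrategyResult:
    """Discounted lifetime cost and QALYs for one cohort trace."""
    strategy = strategy or trace.strategy
    horizon = len(trace.person_time)
    disc = discount_factor(np.arange(horizon), ps)

    occ = trace.occupancy
    occ_used = 0.5 * (occ[:-1] + occ[1:]) if ps.config.half_cycle_correction else occ[1:]

    u_vec = state_utility_vector(ps, trace.states)
    qaly_cycle = (occ_used @ u_vec) / 12.0

    # acute-cycle utility for extracranial-bleed survivors replaces the
    # utility of the state they return to (on aspirin)
    useq = _sequela_utility(ps)
    u_ech = ps.utilities.u_ech
    u_landing = np.array([
        0.0 if h == "DEAD" else _combine(ps, ps.utilities.u_aspirin, useq[h])
        for h in HEALTH_STATES
    ])
    ech_adj = trace.ech_survivors_by_health @ (u_ech - u_landing) / 12.0
    qaly_cycle = qaly_cycle + ech_adj

    c_vec = state_monthly_cost_vector(ps, trace.states)
    cost_cycle = occ_used @ c_vec
    ev_cost = _event_cost_vector(ps, trace.events.columns)
    cost_cycle = cost_cycle + trace.events.to_numpy() @ ev_cost

    cost = float(disc @ cost_cycle)
    if trace.initial_therapy == "warfarin_genotype":
        cost += ps.costs.genotyping_once

    return StrategyResult(
        strategy=strategy,
        discounted_cost=cost,
        discounted_qalys=float(disc @ qaly_cycle),
        undiscounted_qalys=float(qaly_cycle.sum()),
        life_years=float(trace.person_time.sum()),
    )


def net_monetary_benefit(result: StrategyResult, wtp: float) -> float:
    """``wtp * QALYs - cost``."""
    if wtp < 0:
        raise ValueError("willingness-to-pay must be >= 0")
    return wtp * result.discounted_qalys - result.discounted_cost


@dataclass
class CEATable:
    """Ranked cost-effectiveness results with dominance flags."""

    table: pd.DataFrame
    preferred: Optional[str]
    wtp: float

    def __str__(self) -> str:  # Table-2-shaped human-readable summary
        df = self.table.copy()
        df["cost"] = df["cost"].round(0).astype(int)
        df["qalys"] = df["qalys"].round(3)
        df["icer"] = df["icer"].map(
            lambda x: "" if pd.isna(x) else f"{x:,.0f}"
        )
        return df.to_string(index=False)


def build_cea_table(results: Sequence[StrategyResult], wtp: float) -> CEATable:
    """Dominance analysis and frontier ICERs over >= 2 strategies.

    Strong dominance (more costly and fewer QALYs than some other
    strategy) matches the published decision rule; extended dominance is
    computed and flagged separately.  The preferred strategy is the most
    effective frontier strategy whose ICER does not exceed ``wtp``.
    """
    if len(results) < 2:
        raise ValueError("need at least two strategies")
    rows = pd.DataFrame({
        "strategy": [r.strategy for r in results],
        "cost": [r.discounted_cost for r in results],
        "qalys": [r.discounted_qalys for r in results],
    }).sort_values(["cost", "qalys"], ascending=[True, False]).reset_index(drop=True)

    n = len(rows)
    status = ["frontier"] * n
    dominated_by = [""] * n
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            ci, qi = rows.loc[i, "cost"], rows.loc[i, "qalys"]
            cj, qj = rows.loc[j, "cost"], rows.loc[j, "qalys"]
            if cj <= ci and qj >= qi and (cj < ci or qj > qi):
                status[i] = "dominated"
                dominated_by[i] = rows.loc[j, "strategy"]
                break

    # extended dominance over the non-dominated set
    def _frontier_icers(idx: List[int]):
        icers: Dict[int, float] = {}
        for a, b in zip(idx[:-1], idx[1:]):
            dq = rows.loc[b, "qalys"] - rows.loc[a, "qalys"]
            dc = rows.loc[b, "cost"] - rows.loc[a, "cost"]
            icers[b] = 0.0 if (dq == 0 and dc == 0) else (np.inf if dq == 0 else dc / dq)
        return icers

    active = [i for i in range(n) if status[i] == "frontier"]
    while True:
        icers = _frontier_icers(active)
        changed = False
        for a, b in zip(active[1:-1], active[2:]):
            if icers[a] > icers[b]:
                status[a] = "extended_dominated"
                dominated_by[a] = rows.loc[b, "strategy"]
                active.remove(a)
                changed = True
                break
        if not changed:
            break

    icers = _frontier_icers(active)
    rows["status"] = status
    rows["dominated_by"] = dominated_by
    rows["comparator"] = ""
    rows["icer"] = np.nan
    for a, b in zip(active[:-1], active[1:]):
        rows.loc[b, "icer"] = icers[b]
        rows.loc[b, "comparator"] = rows.loc[a, "strategy"]

    preferred = rows.loc[active[0], "strategy"] if active else None
    for b in active[1:]:
        if rows.loc[b, "icer"] <= wtp:
            preferred = rows.loc[b, "strategy"]
    return CEATable(table=rows, preferred=preferred, wtp=wtp)


def evaluate_strategies(ps: ParameterSet, strategies: Optional[List[str]] = None,
                        tables: Optional[EngineTables] = None) -> Dict[str, StrategyResult]:
    """Run the cohort model and accumulate economics for several strategies."""
    from .markov import run_all_strategies

    traces = run_all_strategies(ps, strategies, tables)
    return {s: accumulate(tr, ps) for s, tr in traces.items()}
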