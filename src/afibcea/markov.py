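"""Monthly-cycle Markov cohort engine.

The state space is the product of a health dimension (well, dyspepsia,
post-MI, three stroke-severity sequela states, post-ICH, the combined
ICH-plus-stroke state, dead) and a current-therapy dimension.  The four
strategies share one transition structure; they differ only in the
therapy the cohort starts on.

Within a cycle, competing events are resolved in a fixed precedence
(background death, then intracranial hemorrhage, extracranial
hemorrhage, ischemic stroke, myocardial infarction, dyspepsia onset)
with multiplicative survival of earlier events, so per-cycle mass is
conserved exactly.  Therapy-switching rules: survivors of any major
bleed stop anticoagulation and continue on aspirin alone (extracranial
bleed survivors return to their prior health state); ischemic-stroke
survivors switch to dabigatran 150 mg, except patients with a bleeding
history (post-ICH), who stay on aspirin and move to the combined
ICH-plus-stroke state.  A new permanent sequela replaces the current one
only when it is at least as severe (utility-floor semantics), so a worse
state is never overwritten by a milder event.

Background mortality comes from an age-indexed life table whose annual
probability is treated as a hazard, scaled by a calibration multiplier,
and converted to a monthly probability.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Tuple

import numpy as np
import pandas as pd

from .event_model import build_event_profiles
from .parameters import ParameterSet, RunConfig, STRATEGIES, THERAPIES

__all__ = [
    "HEALTH_STATES",
    "EngineTables",
    "CohortTrace",
    "transition_step",
    "run_cohort",
    "run_all_strategies",
    "background_mortality_prob",
]

HEALTH_STATES = (
    "WELL",
    "DYSPEPSIA",
    "POST_MI",
    "STROKE_MAJOR",
    "STROKE_MINOR",
    "STROKE_NONE",
    "POST_ICH",
    "POST_ICH_STROKE",
    "DEAD",
)
_LIVING = HEALTH_STATES[:-1]

#: incident-event bookkeeping columns (fractions of cohort per cycle)
EVENT_COLUMNS = (
    "ich", "ich_fatal", "ech", "ech_fatal",
    "stroke", "stroke_fatal", "stroke_major", "stroke_minor", "stroke_none",
    "mi", "mi_fatal", "mi_survived", "dyspepsia_onset", "death_background",
)

_DABI = ("dabigatran_150", "dabigatran_110")


def _sequela_utility(ps: ParameterSet) -> Dict[str, float]:
    """Permanent-sequela utility attached to each living health state."""
    u = ps.utilities
    return {
        "WELL": 1.0,
        "STROKE_NONE": 1.0,  # no residual deficit: well-equivalent utility
        "DYSPEPSIA": u.u_dyspepsia,
        "POST_MI": u.u_mi,
        "STROKE_MINOR": u.u_stroke_minor,
        "STROKE_MAJOR": u.u_stroke_major,
        "POST_ICH": u.u_ich,
        "POST_ICH_STROKE": min(u.u_ich, u.u_stroke_major),
    }


class EngineTables:
    """Precomputed transition and incidence matrices for one parameter set.

    ``E`` is the event-transition matrix over living states (background
    mortality is applied outside, per cycle, since it is the only
    age-dependent input).  ``Q`` maps start-of-cycle occupancy (after
    background-death survival) to incident-event masses.
    """

    def __init__(self, ps: ParameterSet):
        self.states: List[Tuple[str, str]] = [
            (h, t) for h in _LIVING for t in THERAPIES
        ] + [("DEAD", "none")]
        self.index = {s: i for i, s in enumerate(self.states)}
        self.n = len(self.states)
        self.dead = self.index[("DEAD", "none")]
        self.living_mask = np.ones(self.n, dtype=bool)
        self.living_mask[self.dead] = False
        self.health = np.array([h for h, _ in self.states])
        self.therapy = np.array([t for _, t in self.states])

        profiles = build_event_profiles(ps)
        useq = _sequela_utility(ps)
        out = ps.outcomes

        E = np.zeros((self.n, self.n))
        Q = np.zeros((self.n, len(EVENT_COLUMNS)))
        col = {c: j for j, c in enumerate(EVENT_COLUMNS)}
        E[self.dead, self.dead] = 1.0

        for i, (h, tau) in enumerate(self.states[:-1]):
            p = profiles[tau]
            p_ich = p.monthly_p_major_bleed * p.ich_fraction
            p_ech = p.monthly_p_major_bleed * (1.0 - p.ich_fraction)
            m_ich = p_ich
            m_ech = (1.0 - p_ich) * p_ech
            s2 = (1.0 - p_ich) * (1.0 - p_ech)
            m_stroke = s2 * p.monthly_p_stroke
            s3 = s2 * (1.0 - p.monthly_p_stroke)
            m_mi = s3 * p.monthly_p_mi
            s4 = s3 * (1.0 - p.monthly_p_mi)
            if h == "WELL" and tau in _DABI:
                m_dysp = s4 * p.monthly_p_dyspepsia_onset
            else:
                m_dysp = 0.0
            m_stay = 1.0 - m_ich - m_ech - m_stroke - m_mi - m_dysp

            # intracranial hemorrhage
            E[i, self.dead] += m_ich * out.ich_mortality
            if h in ("STROKE_MAJOR", "STROKE_MINOR", "POST_ICH_STROKE"):
                ich_target = "POST_ICH_STROKE"
            else:
                ich_target = "POST_ICH"
            E[i, self.index[(ich_target, "aspirin")]] += m_ich * (1.0 - out.ich_mortality)
            Q[i, col["ich"]] += m_ich
            Q[i, col["ich_fatal"]] += m_ich * out.ich_mortality

            # extracranial hemorrhage: survivors keep their health state, on aspirin
            E[i, self.dead] += m_ech * out.ech_mortality
            E[i, self.index[(h, "aspirin")]] += m_ech * (1.0 - out.ech_mortality)
            Q[i, col["ech"]] += m_ech
            Q[i, col["ech_fatal"]] += m_ech * out.ech_mortality

            # ischemic stroke, split by drawn severity
            sev = p.severity
            E[i, self.dead] += m_stroke * sev.fatal
            Q[i, col["stroke"]] += m_stroke
            Q[i, col["stroke_fatal"]] += m_stroke * sev.fatal
            for sev_name, sev_p, target in (
                ("stroke_major", sev.major, "STROKE_MAJOR"),
                ("stroke_minor", sev.minor, "STROKE_MINOR"),
                ("stroke_none", sev.none, "STROKE_NONE"),
            ):
                mass = m_stroke * sev_p
                Q[i, col[sev_name]] += mass
                if h in ("POST_ICH", "POST_ICH_STROKE"):
                    # bleeding history contraindicates re-anticoagulation
                    E[i, self.index[("POST_ICH_STROKE", "aspirin")]] += mass
                else:
                    new_h = target if useq[target] <= useq[h] else h
                    E[i, self.index[(new_h, "dabigatran_150")]] += mass

            # myocardial infarction: survivors keep therapy
            E[i, self.dead] += m_mi * out.mi_mortality
            new_h = "POST_MI" if useq["POST_MI"] <= useq[h] else h
            E[i, self.index[(new_h, tau)]] += m_mi * (1.0 - out.mi_mortality)
            Q[i, col["mi"]] += m_mi
            Q[i, col["mi_fatal"]] += m_mi * out.mi_mortality
            Q[i, col["mi_survived"]] += m_mi * (1.0 - out.mi_mortality)

            # dyspepsia onset (dabigatran only, from WELL)
            if m_dysp:
                E[i, self.index[("DYSPEPSIA", tau)]] += m_dysp
                Q[i, col["dyspepsia_onset"]] += m_dysp

            E[i, i] += m_stay

        self.E = E
        self.Q = Q
        self.col = col
        # extracranial-bleed survivor mass per unit occupancy, grouped by
        # (unchanged) landing health state -- used for the acute-cycle
        # utility adjustment in the economics layer
        self.q_ech_surv = Q[:, col["ech"]] * (1.0 - out.ech_mortality)
        self.health_group = np.zeros((self.n, len(HEALTH_STATES)))
        for i, (h, _) in enumerate(self.states):
            self.health_group[i, HEALTH_STATES.index(h)] = 1.0


def background_mortality_prob(age: float, ps: ParameterSet) -> float:
    """Monthly background death probability at a given age.

    The tabulated annual probability is scaled by the calibration
    multiplier on the hazard scale and converted with a constant hazard:
    ``1 - exp(-multiplier * q_annual / 12)``.
    """
    q = ps.mortality.annual_prob(age) * ps.config.mortality_multiplier
    return -np.expm1(-q / 12.0)


def transition_step(
    occupancy_row: np.ndarray,
    tables: EngineTables,
    p_bg: float,
) -> Tuple[np.ndarray, Dict[str, float]]:
    """Advance the cohort one cycle; return new occupancy and event masses.

    ``p_bg`` is the monthly background death probability for the cycle.
    """
    occ = np.asarray(occupancy_row, dtype=float)
    if occ.shape != (tables.n,):
        raise ValueError(f"occupancy row must have length {tables.n}")
    if np.any(occ < -1e-12):
        raise ValueError("occupancy contains negative mass")
    if abs(occ.sum() - 1.0) > 1e-9:
        raise ValueError(f"occupancy sums to {occ.sum():.12f}, expected 1")
    nxt, ev = _step(occ, tables, p_bg)
    events = {c: float(ev[j]) for c, j in tables.col.items()}
    return nxt, events


def _step(occ: np.ndarray, tables: EngineTables, p_bg: float):
    alive = occ * tables.living_mask
    surv = alive * (1.0 - p_bg)
    nxt = surv @ tables.E
    nxt[tables.dead] += occ[tables.dead] + alive.sum() * p_bg
    ev = surv @ tables.Q
    ev[tables.col["death_background"]] = alive.sum() * p_bg
    return nxt, ev


@dataclass
class CohortTrace:
    """Per-cycle record of one strategy's cohort simulation.

    ``occupancy`` has ``horizon+1`` rows (row 0 is the initial
    distribution); ``events`` has one row per cycle; ``person_time`` is
    end-of-cycle alive fraction in years.
    """

    strategy: str
    initial_therapy: str
    states: List[Tuple[str, str]]
    occupancy: np.ndarray
    events: pd.DataFrame
    person_time: np.ndarray
    person_time_on_initial: np.ndarray
    events_on_initial: pd.DataFrame
    ech_survivors_by_health: np.ndarray  # cycles x health states
    ages: np.ndarray
    p_background: np.ndarray

    def occupancy_frame(self) -> pd.DataFrame:
        cols = [f"{h}|{t}" for h, t in self.states]
        df = pd.DataFrame(self.occupancy, columns=cols)
        df.insert(0, "age", self.ages)
        df.insert(0, "cycle", np.arange(len(df)))
        return df


def run_cohort(strategy: str, ps: ParameterSet, tables: EngineTables | None = None) -> CohortTrace:
    """Deterministic cohort simulation of one strategy over the horizon."""
    if strategy not in STRATEGIES:
        raise ValueError(f"unknown strategy {strategy!r}; expected one of {sorted(STRATEGIES)}")
    return run_all_strategies(ps, [strategy], tables)[strategy]


def run_all_strategies(
    ps: ParameterSet,
    strategies: List[str] | None = None,
    tables: EngineTables | None = None,
) -> Dict[str, CohortTrace]:
    """Run several strategies sharing one set of engine tables."""
    if strategies is None:
        strategies = list(STRATEGIES)
    if tables is None:
        tables = EngineTables(ps)
    cfg = ps.config
    horizon = cfg.horizon_cycles
    ages = cfg.start_age + np.arange(horizon + 1) / 12.0
    p_bg = np.array([background_mortality_prob(a, ps) for a in ages[:-1]])

    k_strats = len(strategies)
    occ = np.zeros((k_strats, tables.n))
    for j, s in enumerate(strategies):
        occ[j, tables.index[("WELL", STRATEGIES[s])]] = 1.0

    occupancy = np.zeros((horizon + 1, k_strats, tables.n))
    occupancy[0] = occ
    events = np.zeros((horizon, k_strats, len(EVENT_COLUMNS)))
    ech_land = np.zeros((horizon, k_strats, len(HEALTH_STATES)))

    living = tables.living_mask
    dcol = tables.col["death_background"]
    for k in range(horizon):
        alive = occ * living
        surv = alive * (1.0 - p_bg[k])
        nxt = surv @ tables.E
        nxt[:, tables.dead] += occ[:, tables.dead] + alive.sum(axis=1) * p_bg[k]
        events[k] = surv @ tables.Q
        events[k, :, dcol] = alive.sum(axis=1) * p_bg[k]
        ech_land[k] = (surv * tables.q_ech_surv) @ tables.health_group
        occ = nxt
        occupancy[k + 1] = occ

    total = occupancy.sum(axis=2)
    if np.max(np.abs(total - 1.0)) > 1e-9:
        raise RuntimeError("cohort mass not conserved within 1e-9")
    if np.any(occupancy < -1e-12):
        raise RuntimeError("negative occupancy mass")

    traces: Dict[str, CohortTrace] = {}
    for j, s in enumerate(strategies):
        init_t = STRATEGIES[s]
        on_init = tables.therapy == init_t
        occ_s = occupancy[:, j, :]
        ev_s = pd.DataFrame(events[:, j, :], columns=list(EVENT_COLUMNS))
        # event masses attributable to mass still on the initial therapy
        surv_init = (occ_s[:-1] * living * on_init) * (1.0 - p_bg)[:, None]
        q_ev = tables.Q[:, [tables.col["stroke"], tables.col["ich"], tables.col["ech"]]]
        ev_init = surv_init @ q_ev
        ev_init_df = pd.DataFrame(ev_init, columns=["stroke", "ich", "ech"])
        ev_init_df["bleed"] = ev_init_df["ich"] + ev_init_df["ech"]
        traces[s] = CohortTrace(
            strategy=s,
            initial_therapy=init_t,
            states=tables.states,
            occupancy=occ_s,
            events=ev_s,
            person_time=occ_s[1:, living].sum(axis=1) / 12.0,
            person_time_on_initial=occ_s[1:, living & on_init].sum(axis=1) / 12.0,
            events_on_initial=ev_init_df,
            ech_survivors_by_health=ech_land[:, j, :],
            ages=ages,
            p_background=p_bg,
        )
    return traces
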