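"""Model inputs: definition, loading, validation, serialization.

Every quantity used anywhere in the model lives here.  Parameters are
stored exactly as published annual rates, fractions, relative risks,
utilities, and USD costs; all unit conversion (annual rate -> monthly
probability, hazard scaling) happens downstream in :mod:`afibcea.event_model`
and :mod:`afibcea.markov`, never at load time.

A parameter file is a nested YAML/JSON mapping.  A leaf may be either a
plain scalar (fixed parameter) or a mapping ``{value: x, range: [lo, hi]}``
declaring the deterministic/probabilistic sensitivity range.  The packaged
``base_case.yaml`` transcribes the published input table; the packaged
``life_table.csv`` supplies age-indexed annual background death
probabilities (two columns: age, annual death probability).
"""

from __future__ import annotations

import copy
import logging
import math
from importlib import resources
from pathlib import Path
from typing import Any, Dict, List, Optional, Tuple, Union

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict

logger = logging.getLogger(__name__)

#: therapy identifiers used throughout the model
THERAPIES = (
    "warfarin_usual",
    "warfarin_genotype",
    "dabigatran_150",
    "dabigatran_110",
    "aspirin",
)

#: strategy id -> therapy the cohort starts on
STRATEGIES = {
    "usual_ac": "warfarin_usual",
    "genotype_ac": "warfarin_genotype",
    "dabigatran_150": "dabigatran_150",
    "dabigatran_110": "dabigatran_110",
}

_SEVERITY_RENORM_TOL = 5e-3  # published rounding slack before renormalizing


class _Model(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=False)


class InrControlParams(_Model):
    """INR control on warfarin.

    ``ttr_*`` are fractions of patient-time with INR in the 2-3 target
    band; ``frac_below_of_out`` is the share of out-of-range time spent
    below range; ``prev_normal_sensitivity`` is the prevalence of
    wild-type CYP2C9/VKORC1 (normal warfarin sensitivity), which weights
    the intensified-monitoring cost in the genotype-guided arm.
    """

    ttr_usual: float
    ttr_genotype: float
    frac_below_of_out: float
    prev_normal_sensitivity: float


class EventRateParams(_Model):
    """Annual event rates (per patient-year, as fractions) and relative risks."""

    stroke_rate_in_range: float
    rr_stroke_below: float
    rr_stroke_above: float
    bleed_rate_in_range: float
    rr_bleed_above: float
    rr_bleed_below: float
    stroke_rate_aspirin: float
    rr_bleed_aspirin_vs_warfarin: float
    rr_stroke_d150: float
    rr_stroke_d110: float
    rr_bleed_d150: float
    rr_bleed_d110: float
    mi_rate_warfarin: float
    mi_rate_aspirin: float
    mi_rate_d150: float
    mi_rate_d110: float
    # Dyspepsia is a modelled health state but no onset incidence is
    # published; rates default to 0 and are opt-in per therapy.
    dyspepsia_rate_by_therapy: Dict[str, float] = {t: 0.0 for t in THERAPIES}


class SeverityDistribution(_Model):
    """Outcome split of an incident ischemic stroke."""

    fatal: float
    major: float
    minor: float
    none: float

    def as_dict(self) -> Dict[str, float]:
        return {
            "fatal": self.fatal,
            "major": self.major,
            "minor": self.minor,
            "none": self.none,
        }

    def total(self) -> float:
        return self.fatal + self.major + self.minor + self.none

    def renormalize(self) -> None:
        s = self.total()
        if s <= 0:
            raise ValueError("stroke severity distribution has non-positive mass")
        if abs(s - 1.0) > 1e-12:
            self.fatal /= s
            self.major /= s
            self.minor /= s
            self.none /= s


class EventOutcomeParams(_Model):
    """Consequences of incident events: severity splits and case fatality."""

    stroke_severity_anticoag: SeverityDistribution
    stroke_severity_aspirin: SeverityDistribution
    ich_fraction_by_therapy: Dict[str, float]  # keys: warfarin, dabigatran_150, dabigatran_110, aspirin
    ich_mortality: float
    ech_mortality: float
    mi_mortality: float


class UtilityParams(_Model):
    """Health-state utilities on the 0 (dead) to 1 (perfect health) scale.

    Therapy utilities (warfarin/dabigatran/aspirin) apply while event-free
    on that therapy; sequela utilities apply to permanent post-event
    states.  No published value exists for aspirin therapy; it defaults to
    1.0 on the same reasoning applied to dabigatran (no routine INR
    monitoring burden) and is configurable.
    """

    u_warfarin: float
    u_dabigatran: float
    u_aspirin: float = 1.0
    u_ich: float
    u_ech: float
    u_stroke_major: float
    u_stroke_minor: float
    u_mi: float
    u_dyspepsia: float
    u_dead: float = 0.0


class CostParams(_Model):
    """Direct medical costs in USD (healthcare-payer perspective)."""

    genotyping_once: float
    ac_monthly: float
    intensified_multiplier: float
    warfarin_monthly: float
    dabigatran_monthly: float
    aspirin_monthly: float = 0.0  # not published; opt-in
    dabigatran_monitoring_monthly: float = 0.0  # none by default (no routine INR testing)
    onetime_ich: float
    onetime_ech: float
    onetime_stroke_major: float
    onetime_stroke_minor: float
    onetime_stroke_none: float
    onetime_mi_survived: float
    onetime_mi_dead: float
    monthly_ich: float
    monthly_stroke_major: float
    monthly_stroke_minor: float
    monthly_ich_and_stroke: float


class MortalityTable(_Model):
    """Age-indexed annual background death probabilities.

    Linear interpolation between integer ages; querying outside the
    tabulated span is an error.
    """

    ages: List[float]
    annual_q: List[float]

    def annual_prob(self, age: float) -> float:
        if age < self.ages[0] or age > self.ages[-1]:
            raise ValueError(
                f"age {age} outside mortality table span "
                f"[{self.ages[0]}, {self.ages[-1]}]"
            )
        return float(np.interp(age, self.ages, self.annual_q))


class RunConfig(_Model):
    """Cohort and analysis configuration."""

    start_age: float = 65.0
    horizon_cycles: int = 300  # 25 years of monthly cycles
    cycle_length_months: float = 1.0
    discount_rate_annual: float = 0.03
    wtp_threshold: float = 50_000.0
    half_cycle_correction: bool = False
    mortality_multiplier: float = 1.0  # scalar on the background annual hazard
    utility_combination: str = "product"  # or "minimum"
    psa_distribution: str = "uniform"  # or "beta"
    rng_seed: int = 0


class ParameterSet(_Model):
    """Complete, validated input set for one model run."""

    inr: InrControlParams
    events: EventRateParams
    outcomes: EventOutcomeParams
    utilities: UtilityParams
    costs: CostParams
    config: RunConfig
    mortality: MortalityTable
    #: dotted parameter path -> (low, high) sensitivity bounds
    ranges: Dict[str, Tuple[float, float]] = {}

    # -- generic scalar access used by sensitivity analysis and the PSA --

    def get(self, path: str) -> float:
        obj: Any = self
        for part in path.split("."):
            obj = obj[part] if isinstance(obj, dict) else getattr(obj, part)
        return obj

    def set(self, path: str, value: float) -> None:
        parts = path.split(".")
        obj: Any = self
        for part in parts[:-1]:
            obj = obj[part] if isinstance(obj, dict) else getattr(obj, part)
        if isinstance(obj, dict):
            obj[parts[-1]] = value
        else:
            setattr(obj, parts[-1], value)

    def copy_deep(self) -> "ParameterSet":
        return copy.deepcopy(self)

    def finalize(self) -> None:
        """Re-establish derived invariants after direct field mutation."""
        self.outcomes.stroke_severity_anticoag.renormalize()
        self.outcomes.stroke_severity_aspirin.renormalize()

    def to_config_dict(self) -> Dict[str, Any]:
        """Serialize back to the file schema (values + declared ranges)."""
        out: Dict[str, Any] = {}
        for section in ("inr", "events", "outcomes", "utilities", "costs", "config"):
            out[section] = _attach_ranges(
                getattr(self, section).model_dump(), section, self.ranges
            )
        out["mortality"] = {
            "ages": list(self.mortality.ages),
            "annual_q": list(self.mortality.annual_q),
        }
        return out


def _attach_ranges(node: Any, prefix: str, ranges: Dict[str, Tuple[float, float]]) -> Any:
    if isinstance(node, dict):
        return {k: _attach_ranges(v, f"{prefix}.{k}", ranges) for k, v in node.items()}
    if prefix in ranges:
        lo, hi = ranges[prefix]
        return {"value": node, "range": [lo, hi]}
    return node


# ---------------------------------------------------------------------------
# loading


def _strip_ranges(node: Any, prefix: str, ranges: Dict[str, Tuple[float, float]]) -> Any:
    """Collapse ``{value, range}`` leaves to plain values, recording ranges."""
    if isinstance(node, dict):
        if "value" in node:
            rng = node.get("range")
            if rng is not None:
                lo, hi = float(rng[0]), float(rng[1])
                ranges[prefix] = (lo, hi)
            return node["value"]
        return {k: _strip_ranges(v, f"{prefix}.{k}", ranges) for k, v in node.items()}
    return node


def _packaged(name: str) -> Path:
    return Path(str(resources.files("afibcea").joinpath("data", name)))


def default_parameter_path() -> Path:
    """Path of the packaged base-case parameter file."""
    return _packaged("base_case.yaml")


def load_mortality_table(path: Union[str, Path, None] = None) -> MortalityTable:
    """Read a two-column (age, annual death probability) CSV."""
    path = Path(path) if path is not None else _packaged("life_table.csv")
    ages: List[float] = []
    qx: List[float] = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        a, q = line.split(",")[:2]
        if a.lower() in ("age",):
            continue
        ages.append(float(a))
        qx.append(float(q))
    return MortalityTable(ages=ages, annual_q=qx)


def load_parameters(
    path: Union[str, Path, Dict[str, Any], None] = None,
    mortality_path: Union[str, Path, None] = None,
) -> ParameterSet:
    """Load and validate a parameter file (YAML or JSON dialect).

    ``path`` may also be an already-parsed mapping.  Missing optional
    fields are filled with documented defaults (and the fill logged);
    any invariant violation raises :class:`ValueError` naming the field
    and the constraint.
    """
    if path is None:
        path = default_parameter_path()
    if isinstance(path, dict):
        raw = copy.deepcopy(path)
    else:
        raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ValueError("parameter file does not parse to a mapping")

    ranges: Dict[str, Tuple[float, float]] = {}
    flat = {
        section: _strip_ranges(raw.get(section, {}), section, ranges)
        for section in ("inr", "events", "outcomes", "utilities", "costs", "config")
    }

    for field, default in (("aspirin_monthly", 0.0), ("dabigatran_monitoring_monthly", 0.0)):
        if field not in flat["costs"]:
            logger.warning("costs.%s not supplied; using documented default %s", field, default)
    if "dyspepsia_rate_by_therapy" not in flat["events"]:
        logger.warning("events.dyspepsia_rate_by_therapy not supplied; defaulting to 0 for all therapies")
    if "u_aspirin" not in flat["utilities"]:
        logger.warning("utilities.u_aspirin not supplied; using documented default 1.0")

    if "mortality" in raw:
        mortality = MortalityTable(**raw["mortality"])
    else:
        mortality = load_mortality_table(mortality_path)

    ps = ParameterSet(
        inr=InrControlParams(**flat["inr"]),
        events=EventRateParams(**flat["events"]),
        outcomes=EventOutcomeParams(**flat["outcomes"]),
        utilities=UtilityParams(**flat["utilities"]),
        costs=CostParams(**flat["costs"]),
        config=RunConfig(**flat["config"]),
        mortality=mortality,
        ranges=ranges,
    )

    for dist, label in (
        (ps.outcomes.stroke_severity_anticoag, "outcomes.stroke_severity_anticoag"),
        (ps.outcomes.stroke_severity_aspirin, "outcomes.stroke_severity_aspirin"),
    ):
        s = dist.total()
        if abs(s - 1.0) > _SEVERITY_RENORM_TOL:
            raise ValueError(
                f"{label}: severity distribution sums to {s:.4f}, "
                f"outside renormalization tolerance {_SEVERITY_RENORM_TOL}"
            )
        if abs(s - 1.0) > 1e-9:
            logger.info("%s sums to %.4f; renormalizing to 1", label, s)
            dist.renormalize()
        # renormalization can push a component a hair past its published
        # range; widen the declared range minimally to keep it contained
        for comp, base in dist.as_dict().items():
            p = f"{label}.{comp}"
            if p in ps.ranges:
                lo, hi = ps.ranges[p]
                ps.ranges[p] = (min(lo, base), max(hi, base))

    violations = validate_ranges(ps)
    if violations:
        raise ValueError("invalid parameter set:\n" + "\n".join(violations))
    return ps


# ---------------------------------------------------------------------------
# validation


def _check(violations: List[str], ok: bool, msg: str) -> None:
    if not ok:
        violations.append(msg)


def validate_ranges(ps: ParameterSet) -> List[str]:
    """Return a list of invariant violations (empty iff the set is valid).

    Purely reporting: never raises.  Each violation names the field, its
    value, and the violated bound.
    """
    v: List[str] = []
    fractions = {
        "inr.ttr_usual": ps.inr.ttr_usual,
        "inr.ttr_genotype": ps.inr.ttr_genotype,
        "inr.frac_below_of_out": ps.inr.frac_below_of_out,
        "inr.prev_normal_sensitivity": ps.inr.prev_normal_sensitivity,
        "outcomes.ich_mortality": ps.outcomes.ich_mortality,
        "outcomes.ech_mortality": ps.outcomes.ech_mortality,
        "outcomes.mi_mortality": ps.outcomes.mi_mortality,
        **{
            f"outcomes.ich_fraction_by_therapy.{k}": val
            for k, val in ps.outcomes.ich_fraction_by_therapy.items()
        },
        **{
            f"utilities.{k}": getattr(ps.utilities, k)
            for k in (
                "u_warfarin", "u_dabigatran", "u_aspirin", "u_ich", "u_ech",
                "u_stroke_major", "u_stroke_minor", "u_mi", "u_dyspepsia",
            )
        },
    }
    for name, x in fractions.items():
        _check(v, 0.0 <= x <= 1.0, f"{name} = {x} outside [0, 1]")
    _check(v, ps.utilities.u_dead == 0.0, f"utilities.u_dead = {ps.utilities.u_dead} must be exactly 0")

    rates = {
        "events.stroke_rate_in_range": ps.events.stroke_rate_in_range,
        "events.bleed_rate_in_range": ps.events.bleed_rate_in_range,
        "events.stroke_rate_aspirin": ps.events.stroke_rate_aspirin,
        "events.mi_rate_warfarin": ps.events.mi_rate_warfarin,
        "events.mi_rate_aspirin": ps.events.mi_rate_aspirin,
        "events.mi_rate_d150": ps.events.mi_rate_d150,
        "events.mi_rate_d110": ps.events.mi_rate_d110,
        **{
            f"events.dyspepsia_rate_by_therapy.{k}": val
            for k, val in ps.events.dyspepsia_rate_by_therapy.items()
        },
    }
    for name, x in rates.items():
        _check(v, x >= 0.0, f"{name} = {x} must be >= 0")

    rrs = {
        "events.rr_stroke_below": ps.events.rr_stroke_below,
        "events.rr_stroke_above": ps.events.rr_stroke_above,
        "events.rr_bleed_above": ps.events.rr_bleed_above,
        "events.rr_bleed_below": ps.events.rr_bleed_below,
        "events.rr_bleed_aspirin_vs_warfarin": ps.events.rr_bleed_aspirin_vs_warfarin,
        "events.rr_stroke_d150": ps.events.rr_stroke_d150,
        "events.rr_stroke_d110": ps.events.rr_stroke_d110,
        "events.rr_bleed_d150": ps.events.rr_bleed_d150,
        "events.rr_bleed_d110": ps.events.rr_bleed_d110,
    }
    for name, x in rrs.items():
        _check(v, x > 0.0, f"{name} = {x} must be > 0")

    for name in (
        "genotyping_once", "ac_monthly", "intensified_multiplier",
        "warfarin_monthly", "dabigatran_monthly", "aspirin_monthly",
        "dabigatran_monitoring_monthly", "onetime_ich", "onetime_ech",
        "onetime_stroke_major", "onetime_stroke_minor", "onetime_stroke_none",
        "onetime_mi_survived", "onetime_mi_dead", "monthly_ich",
        "monthly_stroke_major", "monthly_stroke_minor", "monthly_ich_and_stroke",
    ):
        x = getattr(ps.costs, name)
        _check(v, x >= 0.0, f"costs.{name} = {x} must be >= 0")

    for dist, label in (
        (ps.outcomes.stroke_severity_anticoag, "outcomes.stroke_severity_anticoag"),
        (ps.outcomes.stroke_severity_aspirin, "outcomes.stroke_severity_aspirin"),
    ):
        for k, x in dist.as_dict().items():
            _check(v, 0.0 <= x <= 1.0, f"{label}.{k} = {x} outside [0, 1]")
        s = dist.total()
        _check(v, abs(s - 1.0) <= 1e-6, f"{label} sums to {s:.6f}, must sum to 1")

    cfg = ps.config
    _check(v, cfg.horizon_cycles > 0, f"config.horizon_cycles = {cfg.horizon_cycles} must be > 0")
    _check(v, 0.0 <= cfg.discount_rate_annual < 1.0,
           f"config.discount_rate_annual = {cfg.discount_rate_annual} outside [0, 1)")
    _check(v, cfg.mortality_multiplier >= 0.0,
           f"config.mortality_multiplier = {cfg.mortality_multiplier} must be >= 0")
    _check(v, cfg.wtp_threshold >= 0.0, f"config.wtp_threshold = {cfg.wtp_threshold} must be >= 0")
    _check(v, cfg.utility_combination in ("product", "minimum"),
           f"config.utility_combination = {cfg.utility_combination!r} not in ('product', 'minimum')")

    mt = ps.mortality
    _check(v, len(mt.ages) == len(mt.annual_q) and len(mt.ages) >= 2,
           "mortality table needs >= 2 (age, q) rows of equal length")
    if len(mt.ages) == len(mt.annual_q):
        qs = np.asarray(mt.annual_q)
        _check(v, bool(np.all((qs >= 0) & (qs <= 1))), "mortality probabilities must lie in [0, 1]")
        _check(v, bool(np.all(np.diff(qs) >= 0)), "mortality probabilities must be non-decreasing with age")
        _check(v, bool(np.all(np.diff(mt.ages) > 0)), "mortality table ages must be strictly increasing")

    for path, (lo, hi) in ps.ranges.items():
        _check(v, lo <= hi, f"{path}: range low {lo} exceeds high {hi}")
        try:
            base = ps.get(path)
        except AttributeError:
            v.append(f"{path}: declared range refers to unknown parameter")
            continue
        _check(v, lo - 1e-12 <= base <= hi + 1e-12,
               f"{path} = {base} outside its declared range [{lo}, {hi}]")

    return v
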