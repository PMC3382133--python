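"""Deterministic one-way and two-way sensitivity analysis with threshold search.

One-way analysis sweeps a single ranged parameter across its declared
bounds, re-running the full model at every grid point, and reports the
incremental cost-effectiveness ratio of dabigatran 150 mg versus
genotype-guided anticoagulation care (the frontier comparison of the
base case).  Threshold search locates the parameter value at which that
ICER crosses a target (typically the willingness-to-pay).  Two-way
analysis labels each cell of a parameter-pair grid with the preferred
strategy (highest net monetary benefit among all four).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .economics import evaluate_strategies, net_monetary_benefit
from .parameters import ParameterSet

__all__ = ["OwsaResult", "TwoWayGrid", "one_way", "find_threshold", "two_way", "icer_d150_vs_genotype"]

#: sentinel meanings: -inf = dabigatran 150 dominant, +inf = dominated


def icer_d150_vs_genotype(ps: ParameterSet) -> float:
    """ICER of dabigatran 150 mg vs genotype-guided care; signed-infinity
    sentinels when one strategy dominates the other."""
    res = evaluate_strategies(ps, ["genotype_ac", "dabigatran_150"])
    dq = res["dabigatran_150"].discounted_qalys - res["genotype_ac"].discounted_qalys
    dc = res["dabigatran_150"].discounted_cost - res["genotype_ac"].discounted_cost
    if dq > 0 and dc <= 0:
        return -np.inf  # dominant
    if dq <= 0 and dc >= 0:
        return np.inf  # dominated
    return dc / dq


def _require_range(ps: ParameterSet, param: str) -> Tuple[float, float]:
    if param not in ps.ranges:
        raise ValueError(f"parameter {param!r} has no declared sensitivity range")
    return ps.ranges[param]


def _eval_at(ps: ParameterSet, param: str, value: float) -> float:
    trial = ps.copy_deep()
    trial.set(param, value)
    trial.finalize()
    return icer_d150_vs_genotype(trial)


@dataclass
class OwsaResult:
    parameter: str
    values: np.ndarray
    icers: np.ndarray
    base_value: float
    base_icer: float
    wtp: float
    threshold_crossings: List[float]

    @property
    def icer_low(self) -> float:
        finite = self.icers[np.isfinite(self.icers)]
        return float(finite.min()) if finite.size else np.nan

    @property
    def icer_high(self) -> float:
        finite = self.icers[np.isfinite(self.icers)]
        return float(finite.max()) if finite.size else np.nan

    @property
    def swing(self) -> float:
        return self.icer_high - self.icer_low

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "parameter": self.parameter,
            "value": self.values,
            "icer_d150_vs_genotype": self.icers,
        })


def one_way(ps: ParameterSet, param: str, n_points: int = 25) -> OwsaResult:
    """Sweep ``param`` over its declared range, all else at base case."""
    lo, hi = _require_range(ps, param)
    values = np.linspace(lo, hi, n_points) if hi > lo else np.array([lo])
    icers = np.array([_eval_at(ps, param, v) for v in values])
    base_value = ps.get(param)
    base_icer = icer_d150_vs_genotype(ps)

    wtp = ps.config.wtp_threshold
    crossings: List[float] = []
    sign = np.sign(icers - wtp)
    for i in range(len(values) - 1):
        if np.isfinite(icers[i]) and np.isfinite(icers[i + 1]) and sign[i] * sign[i + 1] < 0:
            x = _bisect(lambda v: _eval_at(ps, param, v) - wtp, values[i], values[i + 1])
            if x is not None:
                crossings.append(x)
    return OwsaResult(
        parameter=param, values=values, icers=icers,
        base_value=base_value, base_icer=base_icer, wtp=wtp,
        threshold_crossings=crossings,
    )


def _bisect(f, a: float, b: float, tol: float = 1.0, max_iter: int = 100) -> Optional[float]:
    fa, fb = f(a), f(b)
    if not (np.isfinite(fa) and np.isfinite(fb)) or fa * fb > 0:
        return None
    for _ in range(max_iter):
        m = 0.5 * (a + b)
        fm = f(m)
        if np.isfinite(fm) and abs(fm) < tol:
            return m
        if not np.isfinite(fm) or fa * fm <= 0:
            b, fb = m, fm if np.isfinite(fm) else fb
        else:
            a, fa = m, fm
        if b - a < 1e-12:
            return 0.5 * (a + b)
    return 0.5 * (a + b)


def find_threshold(
    ps: ParameterSet,
    param: str,
    target_icer: Optional[float] = None,
    n_scan: int = 25,
):
    """Parameter value at which the ICER crosses ``target_icer``.

    Returns a float for a single crossing, ``None`` when the ICER never
    reaches the target inside the declared range, and (with a warning) a
    list of values when the ICER is non-monotone with several crossings.
    """
    lo, hi = _require_range(ps, param)
    if target_icer is None:
        target_icer = ps.config.wtp_threshold
    values = np.linspace(lo, hi, n_scan)
    icers = np.array([_eval_at(ps, param, v) for v in values])
    finite = icers[np.isfinite(icers)]
    monotone = finite.size < 2 or bool(
        np.all(np.diff(finite) >= -1e-9) or np.all(np.diff(finite) <= 1e-9)
    )

    crossings: List[float] = []
    g = lambda v: _eval_at(ps, param, v) - target_icer
    diff = icers - target_icer
    for i in range(len(values) - 1):
        di, dj = diff[i], diff[i + 1]
        if np.isfinite(di) and np.isfinite(dj) and di * dj <= 0 and not (di == 0 and dj == 0):
            x = _bisect(g, values[i], values[i + 1])
            if x is not None and not any(abs(x - c) < 1e-9 for c in crossings):
                crossings.append(x)
    if not crossings:
        return None
    if len(crossings) > 1 and not monotone:
        warnings.warn(
            f"ICER is non-monotone in {param}; returning all {len(crossings)} crossings"
        )
        return crossings
    return crossings[0]


@dataclass
class TwoWayGrid:
    param_a: str
    param_b: str
    values_a: np.ndarray
    values_b: np.ndarray
    preferred: np.ndarray  # (len(a), len(b)) strategy labels
    wtp: float

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, va in enumerate(self.values_a):
            for j, vb in enumerate(self.values_b):
                rows.append((va, vb, self.preferred[i, j]))
        return pd.DataFrame(rows, columns=[self.param_a, self.param_b, "preferred"])


def two_way(
    ps: ParameterSet,
    param_a: str,
    param_b: str,
    n_points: Tuple[int, int] = (41, 41),
) -> TwoWayGrid:
    """Preferred strategy (max net monetary benefit) per grid cell."""
    lo_a, hi_a = _require_range(ps, param_a)
    lo_b, hi_b = _require_range(ps, param_b)
    na, nb = n_points
    va = np.linspace(lo_a, hi_a, na) if hi_a > lo_a else np.array([lo_a])
    vb = np.linspace(lo_b, hi_b, nb) if hi_b > lo_b else np.array([lo_b])
    wtp = ps.config.wtp_threshold
    preferred = np.empty((len(va), len(vb)), dtype=object)
    for i, a in enumerate(va):
        for j, b in enumerate(vb):
            trial = ps.copy_deep()
            trial.set(param_a, float(a))
            trial.set(param_b, float(b))
            trial.finalize()
            res = evaluate_strategies(trial)
            nmbs = {s: net_monetary_benefit(r, wtp) for s, r in res.items()}
            preferred[i, j] = max(nmbs, key=nmbs.get)
    return TwoWayGrid(param_a, param_b, va, vb, preferred, wtp)
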