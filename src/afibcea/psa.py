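"""Probabilistic sensitivity analysis.

Every ranged parameter is drawn independently — uniform over its
declared sensitivity bounds by default, the only distribution implied by
published ranges alone (a symmetric scaled Beta(2,2) is available as a
robustness option).  Stroke-severity draws are renormalized to sum to
one.  Each iteration re-runs the full four-strategy model; the sample
set feeds cost-effectiveness acceptability curves and paired
cost/QALY difference statistics.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .economics import accumulate
from .markov import EngineTables, run_all_strategies
from .parameters import ParameterSet, STRATEGIES

__all__ = ["PsaSampleSet", "CeacCurve", "sample_parameters", "run_psa", "ceac", "paired_differences"]


def _draw(rng: np.random.Generator, lo: float, hi: float, distribution: str) -> float:
    if hi <= lo:
        return lo
    if distribution == "uniform":
        return float(rng.uniform(lo, hi))
    if distribution == "beta":
        return float(lo + (hi - lo) * rng.beta(2.0, 2.0))
    raise ValueError(f"unknown PSA distribution {distribution!r}")


def sample_parameters(ps: ParameterSet, rng: np.random.Generator) -> ParameterSet:
    """One random parameter set: every ranged scalar drawn independently.

    Unranged scalars stay fixed; derived invariants (severity
    distributions summing to one) are re-established after drawing.
    """
    sampled = ps.copy_deep()
    for path in sorted(ps.ranges):
        lo, hi = ps.ranges[path]
        sampled.set(path, _draw(rng, lo, hi, ps.config.psa_distribution))
    sampled.finalize()
    return sampled


@dataclass
class PsaSampleSet:
    """Monte Carlo draws with per-iteration strategy outcomes."""

    n_iterations: int
    seed: int
    strategies: List[str]
    costs: np.ndarray  # (n, n_strategies)
    qalys: np.ndarray  # (n, n_strategies)
    digests: List[str]  # per-iteration digest of the sampled parameter vector

    def to_frame(self) -> pd.DataFrame:
        data = {"iteration": np.arange(self.n_iterations), "digest": self.digests}
        for j, s in enumerate(self.strategies):
            data[f"cost_{s}"] = self.costs[:, j]
            data[f"qalys_{s}"] = self.qalys[:, j]
        return pd.DataFrame(data)


def _digest(values: Sequence[float]) -> str:
    return hashlib.sha256(np.asarray(values, dtype=np.float64).tobytes()).hexdigest()[:16]


def run_psa(ps: ParameterSet, n: int, seed: Optional[int] = None) -> PsaSampleSet:
    """``n`` independent parameter draws, four strategy evaluations each."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if seed is None:
        seed = ps.config.rng_seed
    rng = np.random.default_rng(seed)
    strategies = list(STRATEGIES)
    costs = np.zeros((n, len(strategies)))
    qalys = np.zeros((n, len(strategies)))
    digests: List[str] = []
    paths = sorted(ps.ranges)
    for i in range(n):
        sampled = sample_parameters(ps, rng)
        digests.append(_digest([sampled.get(p) for p in paths]))
        traces = run_all_strategies(sampled, strategies)
        for j, s in enumerate(strategies):
            r = accumulate(traces[s], sampled)
            costs[i, j] = r.discounted_cost
            qalys[i, j] = r.discounted_qalys
    return PsaSampleSet(
        n_iterations=n, seed=seed, strategies=strategies,
        costs=costs, qalys=qalys, digests=digests,
    )


@dataclass
class CeacCurve:
    """Probability each strategy attains the highest net monetary benefit."""

    wtp_grid: np.ndarray
    probabilities: pd.DataFrame  # index: wtp, columns: strategies

    def to_frame(self) -> pd.DataFrame:
        df = self.probabilities.copy()
        df.insert(0, "wtp", self.wtp_grid)
        return df.reset_index(drop=True)


def ceac(samples: PsaSampleSet, wtp_grid: Optional[Sequence[float]] = None) -> CeacCurve:
    """Acceptability curve over a willingness-to-pay grid (ties split equally)."""
    if samples.n_iterations < 1:
        raise ValueError("empty sample set")
    if wtp_grid is None:
        wtp_grid = np.linspace(0.0, 150_000.0, 31)
    wtp_grid = np.asarray(wtp_grid, dtype=float)
    n, k = samples.costs.shape
    probs = np.zeros((len(wtp_grid), k))
    for i, w in enumerate(wtp_grid):
        nmb = w * samples.qalys - samples.costs
        best = nmb.max(axis=1, keepdims=True)
        winners = np.isclose(nmb, best, rtol=0.0, atol=1e-9)
        probs[i] = (winners / winners.sum(axis=1, keepdims=True)).mean(axis=0)
    return CeacCurve(
        wtp_grid=wtp_grid,
        probabilities=pd.DataFrame(probs, columns=samples.strategies),
    )


def paired_differences(
    samples: PsaSampleSet, a: str, b: str, ci: float = 0.95
) -> Dict[str, float]:
    """Per-iteration paired (a - b) cost and QALY differences.

    Returns means and percentile confidence bounds.
    """
    for s in (a, b):
        if s not in samples.strategies:
            raise ValueError(f"strategy {s!r} not in sample set")
    ia, ib = samples.strategies.index(a), samples.strategies.index(b)
    dc = samples.costs[:, ia] - samples.costs[:, ib]
    dq = samples.qalys[:, ia] - samples.qalys[:, ib]
    lo_q, hi_q = 100 * (1 - ci) / 2, 100 * (1 + ci) / 2
    return {
        "mean_dcost": float(dc.mean()),
        "dcost_lo": float(np.percentile(dc, lo_q)),
        "dcost_hi": float(np.percentile(dc, hi_q)),
        "mean_dqalys": float(dq.mean()),
        "dqalys_lo": float(np.percentile(dq, lo_q)),
        "dqalys_hi": float(np.percentile(dq, hi_q)),
    }
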