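"""Discounting, accumulation closed forms, dominance analysis, NMB."""

import numpy as np
import pytest

from afibcea.economics import (
    StrategyResult,
    accumulate,
    build_cea_table,
    discount_factor,
    net_monetary_benefit,
)
from afibcea.markov import run_cohort


def _r(name, cost, qalys):
    return StrategyResult(name, cost, qalys, qalys, qalys)


class TestDiscountFactor:
    def test_values(self, ps):
        assert discount_factor(0, ps) == 1.0
        assert discount_factor(12, 0.03) == pytest.approx(1 / 1.03, abs=1e-9)
        assert discount_factor(12, 0.0) == 1.0
        cycles = np.arange(0, 301)
        d = discount_factor(cycles, ps)
        assert np.all(np.diff(d) < 0)


class TestAccumulateClosedForms:
    @pytest.fixture()
    def short_quiet(self, quiet_ps):
        z = quiet_ps.copy_deep()
        z.config.horizon_cycles = 12
        z.config.discount_rate_annual = 0.0
        return z

    def test_warfarin_year(self, short_quiet):
        trace = run_cohort("usual_ac", short_quiet)
        res = accumulate(trace, short_quiet)
        assert res.discounted_qalys == pytest.approx(0.95, abs=1e-9)
        assert res.discounted_cost == pytest.approx(12 * (31 + 6), abs=1e-9)

    def test_dabigatran_year(self, short_quiet):
        trace = run_cohort("dabigatran_150", short_quiet)
        res = accumulate(trace, short_quiet)
        assert res.discounted_qalys == pytest.approx(1.0, abs=1e-9)
        assert res.discounted_cost == pytest.approx(12 * 240, abs=1e-9)

    def test_genotype_year_adds_genotyping_and_weighted_monitoring(self, short_quiet):
        trace = run_cohort("genotype_ac", short_quiet)
        res = accumulate(trace, short_quiet)
        monitoring = 31 * (0.292 + 0.708 * 2)  # 52.948 USD/month
        assert res.discounted_cost == pytest.approx(72 + 12 * (6 + monitoring), abs=1e-9)

    def test_unit_utilities_make_qalys_equal_person_time(self, ps):
        flat = ps.copy_deep()
        flat.config.discount_rate_annual = 0.0
        u = flat.utilities
        for f in ("u_warfarin", "u_dabigatran", "u_aspirin", "u_ich", "u_ech",
                  "u_stroke_major", "u_stroke_minor", "u_mi", "u_dyspepsia"):
            setattr(u, f, 1.0)
        trace = run_cohort("usual_ac", flat)
        res = accumulate(trace, flat)
        assert res.discounted_qalys == pytest.approx(trace.person_time.sum(), abs=1e-9)

    def test_discounted_totals_below_undiscounted(self, ps, traces, results):
        for s, res in results.items():
            assert res.discounted_qalys <= res.undiscounted_qalys
            assert 0 <= res.discounted_qalys <= ps.config.horizon_cycles / 12


class TestCeaTable:
    def test_published_pairs_reproduce_dominance_and_icer(self):
        results = [
            _r("genotype_ac", 85_627, 9.554),
            _r("usual_ac", 90_481, 9.444),
            _r("dabigatran_150", 92_684, 10.065),
            _r("dabigatran_110", 102_536, 10.026),
        ]
        cea = build_cea_table(results, 50_000)
        t = cea.table.set_index("strategy")
        assert t.loc["usual_ac", "status"] == "dominated"
        assert t.loc["usual_ac", "dominated_by"] == "genotype_ac"
        assert t.loc["dabigatran_110", "status"] == "dominated"
        assert t.loc["dabigatran_110", "dominated_by"] == "dabigatran_150"
        assert t.loc["dabigatran_150", "icer"] == pytest.approx(13_810, abs=1.0)
        assert t.loc["dabigatran_150", "comparator"] == "genotype_ac"
        assert cea.preferred == "dabigatran_150"

    def test_equal_qalys_prefers_cheaper_without_icer(self):
        cea = build_cea_table([_r("a", 100.0, 5.0), _r("b", 200.0, 5.0)], 50_000)
        t = cea.table.set_index("strategy")
        assert t.loc["b", "status"] == "dominated"
        assert cea.preferred == "a"
        assert np.isnan(t.loc["a", "icer"])

    def test_exact_tie_keeps_both_with_zero_icer(self):
        cea = build_cea_table([_r("a", 100.0, 5.0), _r("b", 100.0, 5.0)], 50_000)
        assert set(cea.table["status"]) == {"frontier"}
        assert cea.table["icer"].fillna(0.0).max() == 0.0

    def test_frontier_matches_brute_force_dominance_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(25):
            pts = [(float(c), float(q)) for c, q in
                   zip(rng.uniform(0, 1e5, 6), rng.uniform(0, 12, 6))]
            results = [_r(f"s{i}", c, q) for i, (c, q) in enumerate(pts)]
            cea = build_cea_table(results, 50_000)
            t = cea.table.set_index("strategy")
            for i, (ci, qi) in enumerate(pts):
                dominated = any(
                    (cj <= ci and qj >= qi and (cj < ci or qj > qi))
                    for j, (cj, qj) in enumerate(pts) if j != i
                )
                assert (t.loc[f"s{i}", "status"] == "dominated") == dominated
            front = cea.table[cea.table["status"] == "frontier"]
            icers = front["icer"].dropna().to_numpy()
            assert np.all(np.diff(front["cost"]) >= 0)
            assert np.all(np.diff(front["qalys"]) >= 0)
            assert np.all(np.diff(icers) >= -1e-9)

    def test_icer_invariant_to_constant_cost_shift(self):
        base = [_r("a", 1000.0, 5.0), _r("b", 2000.0, 6.0)]
        shifted = [_r("a", 51000.0, 5.0), _r("b", 52000.0, 6.0)]
        i1 = build_cea_table(base, 1).table.set_index("strategy").loc["b", "icer"]
        i2 = build_cea_table(shifted, 1).table.set_index("strategy").loc["b", "icer"]
        assert i1 == pytest.approx(i2)

    def test_requires_two_strategies(self):
        with pytest.raises(ValueError):
            build_cea_table([_r("a", 1.0, 1.0)], 50_000)


class TestNetMonetaryBenefit:
    def test_published_arithmetic(self):
        assert net_monetary_benefit(_r("g", 85_627, 9.554), 50_000) == pytest.approx(392_073)
        assert net_monetary_benefit(_r("d", 92_684, 10.065), 50_000) == pytest.approx(410_566)

    def test_zero_wtp_is_negative_cost(self):
        assert net_monetary_benefit(_r("g", 123.0, 9.0), 0.0) == -123.0
        with pytest.raises(ValueError):
            net_monetary_benefit(_r("g", 1.0, 1.0), -1.0)

    def test_nmb_and_icer_threshold_preferences_agree(self, results):
        res = list(results.values())
        for wtp in np.linspace(1_000, 150_000, 16):
            cea = build_cea_table(res, wtp)
            by_nmb = max(res, key=lambda r: net_monetary_benefit(r, wtp)).strategy
            assert cea.preferred == by_nmb
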