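"""Cohort engine: mass conservation, transition semantics, background mortality."""

import numpy as np
import pytest

from afibcea.markov import (
    EngineTables,
    background_mortality_prob,
    run_all_strategies,
    run_cohort,
    transition_step,
)
from afibcea.parameters import STRATEGIES


class TestInvariants:
    def test_mass_conserved_every_cycle_every_strategy(self, traces):
        for trace in traces.values():
            totals = trace.occupancy.sum(axis=1)
            assert np.max(np.abs(totals - 1.0)) < 1e-9
            assert np.min(trace.occupancy) >= -1e-12

    def test_dead_occupancy_non_decreasing(self, traces):
        for trace in traces.values():
            dead = trace.occupancy[:, -1]
            assert np.all(np.diff(dead) >= -1e-12)

    def test_no_warfarin_therapy_after_bleed_or_stroke(self, traces):
        # post-event states carry only aspirin or dabigatran-150 therapy
        post_event = {"STROKE_MAJOR", "STROKE_MINOR", "STROKE_NONE", "POST_ICH", "POST_ICH_STROKE"}
        for trace in traces.values():
            for i, (h, t) in enumerate(trace.states):
                if h in post_event and t.startswith("warfarin"):
                    assert np.all(trace.occupancy[:, i] == 0.0), (h, t)

    def test_higher_genotype_ttr_means_more_person_time_fewer_events(self, ps, traces):
        better = ps.copy_deep()
        better.inr.ttr_genotype = 0.90
        tr_hi = run_cohort("genotype_ac", better)
        tr_lo = traces["genotype_ac"]
        assert tr_hi.person_time.sum() > tr_lo.person_time.sum()
        ev_hi = tr_hi.events[["stroke", "ich", "ech"]].to_numpy().sum()
        ev_lo = tr_lo.events[["stroke", "ich", "ech"]].to_numpy().sum()
        assert ev_hi < ev_lo


class TestTransitionStep:
    def test_dead_state_is_absorbing(self, ps):
        tables = EngineTables(ps)
        row = np.zeros(tables.n)
        row[tables.dead] = 1.0
        nxt, events = transition_step(row, tables, p_bg=0.01)
        assert np.array_equal(nxt, row)
        assert all(v == 0.0 for v in events.values())

    def test_identity_when_all_hazards_zero(self, quiet_ps):
        tables = EngineTables(quiet_ps)
        row = np.zeros(tables.n)
        row[tables.index[("WELL", "warfarin_usual")]] = 1.0
        nxt, events = transition_step(row, tables, p_bg=0.0)
        assert np.allclose(nxt, row)
        assert all(v == 0.0 for v in events.values())

    def test_rejects_invalid_rows(self, ps):
        tables = EngineTables(ps)
        with pytest.raises(ValueError, match="sums"):
            transition_step(np.zeros(tables.n), tables, 0.0)
        bad = np.zeros(tables.n)
        bad[0], bad[1] = 1.5, -0.5
        with pytest.raises(ValueError, match="negative"):
            transition_step(bad, tables, 0.0)

    def test_one_cycle_against_micro_simulation(self, ps):
        """Stroke incidence from (WELL, usual warfarin) matches a Monte
        Carlo micro-simulation of the competing-event cascade within 3 SE."""
        tables = EngineTables(ps)
        from afibcea.event_model import build_event_profiles

        prof = build_event_profiles(ps)["warfarin_usual"]
        p_bg = background_mortality_prob(65.0, ps)
        row = np.zeros(tables.n)
        row[tables.index[("WELL", "warfarin_usual")]] = 1.0
        _, events = transition_step(row, tables, p_bg)

        n = 1_000_000
        rng = np.random.default_rng(2024)
        u = rng.random((n, 4))
        alive = u[:, 0] >= p_bg
        p_ich = prof.monthly_p_major_bleed * prof.ich_fraction
        p_ech = prof.monthly_p_major_bleed * (1 - prof.ich_fraction)
        ich = alive & (u[:, 1] < p_ich)
        ech = alive & ~ich & (u[:, 2] < p_ech)
        stroke = alive & ~ich & ~ech & (u[:, 3] < prof.monthly_p_stroke)
        p_hat = stroke.mean()
        se = np.sqrt(p_hat * (1 - p_hat) / n)
        assert abs(events["stroke"] - p_hat) < 3 * se


class TestBackgroundMortality:
    def test_zero_multiplier_kills_nobody(self, ps):
        z = ps.copy_deep()
        z.config.mortality_multiplier = 0.0
        assert background_mortality_prob(70.0, z) == 0.0

    def test_constant_hazard_conversion_and_interpolation(self, ps):
        one = ps.copy_deep()
        one.config.mortality_multiplier = 1.0
        q70 = one.mortality.annual_prob(70.0)
        assert background_mortality_prob(70.0, one) == pytest.approx(
            1 - np.exp(-q70 / 12), abs=1e-12
        )
        q_mid = one.mortality.annual_prob(70.5)
        assert min(q70, one.mortality.annual_prob(71.0)) <= q_mid <= max(
            q70, one.mortality.annual_prob(71.0)
        )

    def test_multiplier_scales_hazard_not_probability(self, ps):
        two = ps.copy_deep()
        two.config.mortality_multiplier = 2.0
        one = ps.copy_deep()
        one.config.mortality_multiplier = 1.0
        q = one.mortality.annual_prob(80.0)
        assert background_mortality_prob(80.0, two) == pytest.approx(
            1 - np.exp(-2 * q / 12), abs=1e-12
        )

    def test_age_outside_table_rejected(self, ps):
        with pytest.raises(ValueError, match="outside"):
            background_mortality_prob(200.0, ps)

    def test_dead_mass_equals_background_survival_product_without_case_fatality(self, ps):
        safe = ps.copy_deep()
        safe.ranges = {}
        safe.outcomes.ich_mortality = 0.0
        safe.outcomes.ech_mortality = 0.0
        safe.outcomes.mi_mortality = 0.0
        sev = safe.outcomes.stroke_severity_anticoag
        sev.major += sev.fatal
        sev.fatal = 0.0
        sev_a = safe.outcomes.stroke_severity_aspirin
        sev_a.major += sev_a.fatal
        sev_a.fatal = 0.0
        trace = run_cohort("usual_ac", safe)
        expected_alive = np.cumprod(1.0 - trace.p_background)
        alive = 1.0 - trace.occupancy[1:, -1]
        assert np.allclose(alive, expected_alive, atol=1e-9)


class TestRunCohort:
    def test_unknown_strategy_rejected(self, ps):
        with pytest.raises(ValueError, match="unknown strategy"):
            run_cohort("placebo", ps)

    def test_quiet_cohort_stays_well(self, quiet_ps):
        trace = run_cohort("dabigatran_150", quiet_ps)
        i = trace.states.index(("WELL", "dabigatran_150"))
        assert np.all(trace.occupancy[:, i] == 1.0)

    def test_usual_care_bleeding_rate_near_partition_value(self, traces):
        from afibcea.validation import simulated_event_rates

        rates = simulated_event_rates(traces["usual_ac"], "on_initial")
        assert rates["bleed"] == pytest.approx(3.39, abs=0.15)

    def test_bleeding_rate_ratio_recovers_relative_risk(self, traces):
        from afibcea.validation import simulated_event_rates

        r110 = simulated_event_rates(traces["dabigatran_110"], "on_initial")
        rusual = simulated_event_rates(traces["usual_ac"], "on_initial")
        assert r110["bleed"] / rusual["bleed"] == pytest.approx(0.80, abs=0.01)

    def test_all_strategies_share_state_space(self, traces):
        assert set(traces) == set(STRATEGIES)
        states = traces["usual_ac"].states
        for tr in traces.values():
            assert tr.states == states
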