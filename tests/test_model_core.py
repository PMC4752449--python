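"""Unit and property tests for the weekly Markov cohort engine."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fncea import (
    HealthState,
    ParameterSet,
    StrategySpec,
    fn_onset_probability,
    gcsf_given,
    run_cohort,
    weekly_transition,
)

S1, SEV, UNC, S4, DEAD = (int(s) for s in HealthState)


def parameter_sets():
    """Hypothesis strategy over valid parameter sets."""
    prob = st.floats(0.0, 1.0, allow_nan=False)
    cost = st.floats(0.0, 50_000.0, allow_nan=False)
    rr = st.floats(0.05, 5.0, allow_nan=False)
    return st.builds(
        ParameterSet,
        cost_pegfilgrastim_per_cycle=cost,
        cost_nivestim_per_cycle=cost,
        cost_hosp_fn_severe=cost,
        cost_hosp_fn_uncomplicated=cost,
        utility_no_fn=prob,
        utility_fn_uncomplicated=prob,
        utility_fn_severe=prob,
        rr_pegfilgrastim=rr,
        rr_nivestim=rr,
        rr_history=rr,
        p_fn_cycle1=prob,
        p_fn_cycle2to6=prob,
        p_severe_given_fn=prob,
        cfr_fn_severe=prob,
        cfr_fn_uncomplicated=prob,
    )


class TestFnOnsetProbability:
    @pytest.mark.parametrize(
        "cycle, agent, on_gcsf, has_history, expected",
        [
            (1, "none", False, False, 0.17),
            (3, "none", False, True, 0.03 * 2.29),
            (1, "pegfilgrastim", True, False, 0.17 * 0.55),
            (2, "nivestim", True, True, 0.03 * 0.62 * 2.29),
        ],
    )
    def test_multiplicative_risk(self, params, cycle, agent, on_gcsf, has_history, expected):
        assert fn_onset_probability(cycle, agent, on_gcsf, has_history, params) == pytest.approx(expected)

    def test_clamped_to_one(self, params):
        boosted = params.replace(p_fn_cycle1=0.9, rr_history=2.29)
        assert fn_onset_probability(1, "none", False, True, boosted) == 1.0

    @pytest.mark.parametrize("cycle", [0, 7, -1])
    def test_cycle_out_of_range(self, params, cycle):
        with pytest.raises(ValueError):
            fn_onset_probability(cycle, "none", False, False, params)


class TestGcsfGiven:
    @pytest.mark.parametrize(
        "strategy_id, cycle, has_history, expected",
        [
            ("pp-nivestim-c12", 2, False, True),
            ("pp-nivestim-c12", 3, False, False),
            ("pp-nivestim-c12", 3, True, True),
            ("sp-pegfilgrastim", 1, False, False),
            ("sp-pegfilgrastim", 4, True, True),
            ("no-prophylaxis", 5, True, False),
            ("pp-pegfilgrastim-all", 6, False, True),
        ],
    )
    def test_schedule_rule(self, by_id, strategy_id, cycle, has_history, expected):
        assert gcsf_given(by_id[strategy_id], cycle, has_history) is expected


class TestWeeklyTransition:
    def test_dead_state_is_absorbing(self, params, by_id):
        occ = np.array([0.0, 0.0, 0.0, 0.0, 1.0])
        for week in range(1, 19):
            occ = weekly_transition(occ, week, by_id["no-prophylaxis"], params)
        assert occ[DEAD] == 1.0

    def test_onset_split_in_cycle_one(self, params, by_id):
        out = weekly_transition([1, 0, 0, 0, 0], 1, by_id["no-prophylaxis"], params)
        assert out[SEV] == pytest.approx(0.17 * 0.14)
        assert out[UNC] == pytest.approx(0.17 * 0.86)
        assert out[S1] == pytest.approx(0.83)
        assert out.sum() == pytest.approx(1.0, abs=1e-12)

    def test_tunnel_exit_splits_to_history_and_death(self, params, by_id):
        occ = [0.83, 0.0238, 0.1462, 0.0, 0.0]
        out = weekly_transition(occ, 2, by_id["no-prophylaxis"], params)
        expected_dead = 0.0238 * 0.025 + 0.1462 * 0.0063
        assert out[DEAD] == pytest.approx(expected_dead)
        assert out[SEV] == out[UNC] == 0.0
        assert out[S4] == pytest.approx(0.17 - expected_dead)

    def test_third_week_is_identity(self, params, by_id):
        occ = np.array([0.7, 0.0, 0.0, 0.25, 0.05])
        out = weekly_transition(occ, 3, by_id["no-prophylaxis"], params)
        np.testing.assert_allclose(out, occ)

    def test_rejects_non_unit_mass(self, params, by_id):
        with pytest.raises(ValueError, match="sum to 1"):
            weekly_transition([0.5, 0, 0, 0, 0], 1, by_id["no-prophylaxis"], params)

    def test_rejects_week_outside_horizon(self, params, by_id):
        with pytest.raises(ValueError, match="week_index"):
            weekly_transition([1, 0, 0, 0, 0], 19, by_id["no-prophylaxis"], params)


class TestRunCohort:
    def test_zero_risk_cohort_accrues_only_drug_cost(self, params, by_id):
        safe = params.replace(p_fn_cycle1=0.0, p_fn_cycle2to6=0.0)
        np_res = run_cohort(by_id["no-prophylaxis"], safe)
        assert np_res.expected_cost == 0.0
        assert np_res.expected_fn_episodes == 0.0
        assert np_res.expected_qalys == pytest.approx(18 * 0.80 / 52)
        assert np_res.survival_fraction == 1.0
        pp = run_cohort(by_id["pp-nivestim-all"], safe)
        assert pp.expected_cost == pytest.approx(6 * safe.cost_nivestim_per_cycle)

    def test_mass_conservation_default_inputs(self, params, strategies):
        for s in strategies:
            trace = run_cohort(s, params).trace
            np.testing.assert_allclose(trace.sum(axis=1), 1.0, atol=1e-12)
            assert trace.min() >= 0.0

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(p=parameter_sets())
    def test_mass_conservation_over_parameter_space(self, strategies, p):
        for s in strategies:
            trace = run_cohort(s, p).trace
            np.testing.assert_allclose(trace.sum(axis=1), 1.0, atol=1e-12)
            assert trace.min() >= -1e-15

    def test_fn_tunnel_occupied_only_in_second_cycle_week(self, params, by_id):
        trace = run_cohort(by_id["no-prophylaxis"], params).trace
        fn_mass = trace[:, SEV] + trace[:, UNC]
        fn_weeks = {w + 1 for w in range(18) if fn_mass[w] > 0}
        assert fn_weeks == {2, 5, 8, 11, 14, 17}

    def test_episode_count_equals_incident_tunnel_mass(self, params, strategies):
        for s in strategies:
            res = run_cohort(s, params)
            fn_mass = res.trace[:, SEV] + res.trace[:, UNC]
            assert res.expected_fn_episodes == pytest.approx(fn_mass.sum())

    def test_qaly_ceiling(self, params, strategies):
        cap = params.horizon_weeks * params.utility_no_fn / 52
        for s in strategies:
            assert run_cohort(s, params).expected_qalys <= cap + 1e-12

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(p=parameter_sets(), scale=st.floats(0.0, 1.0, allow_nan=False))
    def test_scaling_down_risk_never_increases_burden(self, by_id, p, scale):
        strat = by_id["no-prophylaxis"]
        base = run_cohort(strat, p)
        safer = run_cohort(
            strat,
            p.replace(p_fn_cycle1=p.p_fn_cycle1 * scale, p_fn_cycle2to6=p.p_fn_cycle2to6 * scale),
        )
        assert safer.expected_fn_episodes <= base.expected_fn_episodes + 1e-12
        assert safer.cost_hospitalization <= base.cost_hospitalization + 1e-9

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(p=parameter_sets(), scale=st.floats(0.0, 1.0, allow_nan=False))
    def test_survival_non_increasing_in_case_fatality(self, by_id, p, scale):
        strat = by_id["no-prophylaxis"]
        milder = p.replace(
            cfr_fn_severe=p.cfr_fn_severe * scale,
            cfr_fn_uncomplicated=p.cfr_fn_uncomplicated * scale,
        )
        assert (
            run_cohort(strat, milder).survival_fraction
            >= run_cohort(strat, p).survival_fraction - 1e-12
        )

    def test_no_memory_effect_without_history_relative_risk(self, params, by_id):
        """With rr_history = 1 and no deaths, cycles 2-6 incidence is flat."""
        flat = params.replace(rr_history=1.0, cfr_fn_severe=0.0, cfr_fn_uncomplicated=0.0)
        trace = run_cohort(by_id["no-prophylaxis"], flat).trace
        fn_mass = trace[:, SEV] + trace[:, UNC]
        per_cycle = [fn_mass[3 * c - 2] for c in range(2, 7)]
        np.testing.assert_allclose(per_cycle, per_cycle[0], rtol=1e-12)

    def test_secondary_prophylaxis_cannot_alter_first_cycle(self, params, by_id):
        incidences = {}
        for sid in ("no-prophylaxis", "sp-nivestim", "sp-pegfilgrastim"):
            trace = run_cohort(by_id[sid], params).trace
            incidences[sid] = trace[1, SEV] + trace[1, UNC]
        assert incidences["no-prophylaxis"] == pytest.approx(incidences["sp-nivestim"])
        assert incidences["no-prophylaxis"] == pytest.approx(incidences["sp-pegfilgrastim"])

    def test_trace_frame_layout(self, params, by_id):
        frame = run_cohort(by_id["no-prophylaxis"], params).trace_frame()
        assert list(frame.columns) == ["week", "state", "occupancy"]
        assert len(frame) == 18 * 5
        assert frame.groupby("week")["occupancy"].sum().round(12).eq(1.0).all()


class TestValidation:
    def test_agent_none_admits_no_schedule(self):
        with pytest.raises(ValueError):
            StrategySpec(id="bad", agent="none", pp_cycles=frozenset({1}))
        with pytest.raises(ValueError):
            StrategySpec(id="bad", agent="none", sp_enabled=True)

    def test_unknown_agent_rejected(self):
        with pytest.raises(ValueError, match="agent"):
            StrategySpec(id="bad", agent="filgrastim")

    @pytest.mark.parametrize(
        "field, value",
        [
            ("p_fn_cycle1", 1.2),
            ("utility_no_fn", -0.1),
            ("cost_hosp_fn_severe", -5.0),
            ("rr_nivestim", 0.0),
            ("horizon_weeks", 17),
        ],
    )
    def test_parameter_invariants_enforced(self, params, field, value):
        with pytest.raises(ValueError, match=field):
            params.replace(**{field: value})
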