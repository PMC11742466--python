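import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import msmarkov as mm
from msmarkov.engine import InfeasibleAdjustmentError, _step  # noqa: F401
from msmarkov.params import N_EDSS

from conftest import toy_params


class TestAdjustProgression:
    def test_identity_at_hr_one(self):
        row = np.zeros(N_EDSS)
        row[2], row[3] = 0.7, 0.3
        np.testing.assert_allclose(mm.adjust_progression(row, 2, 1.0), row, atol=1e-15)

    def test_halving_worsening(self):
        row = np.zeros(N_EDSS)
        row[2], row[3] = 0.7, 0.3
        out = mm.adjust_progression(row, 2, 0.5)
        assert out[3] == pytest.approx(0.15)
        assert out[2] == pytest.approx(0.85)

    def test_two_step_worsening_example(self):
        row = np.zeros(N_EDSS)
        row[0], row[1], row[2] = 0.8, 0.15, 0.05
        out = mm.adjust_progression(row, 0, 0.46)
        np.testing.assert_allclose(out[:3], [0.908, 0.069, 0.023], atol=1e-12)

    def test_improvement_entries_never_adjusted(self):
        row = np.zeros(N_EDSS)
        row[1], row[2], row[3] = 0.2, 0.5, 0.3
        out = mm.adjust_progression(row, 2, 0.5)
        assert out[1] == 0.2

    def test_infeasible_adjustment(self):
        row = np.zeros(N_EDSS)
        row[0], row[1] = 0.1, 0.9
        with pytest.raises(InfeasibleAdjustmentError, match="infeasible"):
            mm.adjust_progression(row, 0, 1.5)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        raw=st.lists(st.floats(0.01, 1.0), min_size=N_EDSS, max_size=N_EDSS),
        source=st.integers(0, N_EDSS - 1),
        hr=st.floats(0.01, 1.0),
    )
    def test_adjusted_row_is_valid_and_scales_worsening(self, raw, source, hr):
        row = np.asarray(raw) / np.sum(raw)
        row = row / row.sum()
        out = mm.adjust_progression(row, source, hr)
        assert out.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(out >= 0)
        worsen = np.arange(N_EDSS) > source
        np.testing.assert_allclose(out[worsen], row[worsen] * hr, rtol=1e-12)
        np.testing.assert_allclose(out[np.arange(N_EDSS) < source], row[np.arange(N_EDSS) < source])

    def test_rate_space_alternative(self):
        row = np.zeros(N_EDSS)
        row[2], row[3] = 0.7, 0.3
        out = mm.adjust_progression(row, 2, 0.5, method="rate")
        assert out[3] == pytest.approx(1 - 0.7**0.5)
        assert out.sum() == pytest.approx(1.0)


class TestDeathProbability:
    @pytest.mark.parametrize(
        "mult,q,expected", [(1.0, 0.001, 0.001), (3.0, 0.002, 0.006), (3.0, 0.5, 1.0)]
    )
    def test_multiplier_arithmetic_and_cap(self, mult, q, expected):
        p = toy_params(q_death=q, multipliers=np.full(N_EDSS, mult))
        assert mm.death_probability(4, 40.0, p.mortality, 0.7) == pytest.approx(expected)

    def test_sex_mixing(self):
        p = toy_params()
        m = p.mortality
        qf = np.full(m.ages.size, 0.002)
        qm = np.full(m.ages.size, 0.004)
        mixed = mm.MortalityModel(
            ages=m.ages, q_female=qf, q_male=qm,
            le_female=m.le_female, le_male=m.le_male,
            multiplier_by_edss=m.multiplier_by_edss,
        )
        assert mm.death_probability(0, 40.0, mixed, 0.7) == pytest.approx(
            0.7 * 0.002 + 0.3 * 0.004
        )


class TestStepCohort:
    def test_identity_dynamics_only_ages(self):
        p = toy_params()
        s0 = mm.initial_state(p)
        s1 = mm.step_cohort(s0, "NAT", p)
        np.testing.assert_allclose(s1.occupancy, s0.occupancy, atol=1e-15)
        assert s1.dead_mass == 0.0
        assert s1.cohort_age == s0.cohort_age + 1.0

    def test_stop_rule_moves_arrivals_to_bsc(self):
        matrix = np.eye(N_EDSS)
        matrix[6, 6], matrix[6, 7] = 0.8, 0.2
        p = toy_params(matrix=matrix, baseline_edss=6)
        s1 = mm.step_cohort(mm.initial_state(p), "NAT", p)
        assert s1.occupancy[mm.Stratum.BSC, 7] == pytest.approx(0.2)
        assert s1.occupancy[mm.Stratum.ON_TREATMENT, 7] == 0.0
        assert s1.occupancy[mm.Stratum.ON_TREATMENT, 6] == pytest.approx(0.8)

    def test_discontinuation_fraction(self):
        p = toy_params(p_discontinue=0.10)
        s1 = mm.step_cohort(mm.initial_state(p), "NAT", p)
        assert s1.occupancy[mm.Stratum.ON_TREATMENT, 2] == pytest.approx(0.9)
        assert s1.occupancy[mm.Stratum.BSC, 2] == pytest.approx(0.1)

    def test_discontinuation_is_absorbing(self):
        p = toy_params(p_discontinue=0.10)
        s = mm.initial_state(p)
        bsc = []
        for _ in range(5):
            s = mm.step_cohort(s, "NAT", p)
            bsc.append(s.occupancy[mm.Stratum.BSC].sum())
        assert np.all(np.diff(bsc) > 0)  # BSC mass never flows back

    def test_unknown_dmt(self):
        p = toy_params()
        with pytest.raises(mm.ParameterValidationError, match="unknown DMT"):
            mm.step_cohort(mm.initial_state(p), "XYZ", p)


class TestRunScenario:
    def test_neutral_treatment_equals_natural_history(self, default_params):
        import dataclasses

        eff = {
            d: dataclasses.replace(e, hr_cdp6=1.0, p_discontinue=0.0)
            for d, e in default_params.effects.items()
        }
        p = dataclasses.replace(default_params, effects=eff)
        traj = mm.run_scenario(mm.continuous("NAT"), p)
        # pure natural-history propagation of the living distribution
        dist = p.baseline.edss_distribution.copy()
        age = p.baseline.mean_age
        dead = 0.0
        for k in range(p.config.horizon_years):
            q = np.minimum(1.0, p.mortality.multiplier_by_edss
                           * p.mortality.q_general(age, 0.7))
            dead += float(dist @ q)
            dist = (dist * (1 - q)) @ p.natural_history.p
            age += 1
        np.testing.assert_allclose(traj.states[-1].living_by_edss, dist, atol=1e-12)
        assert traj.states[-1].dead_mass == pytest.approx(dead, abs=1e-12)

    def test_half_cycle_effective_is_trapezoid(self):
        matrix = np.eye(N_EDSS)
        matrix[0, 0], matrix[0, 1] = 0.6, 0.4
        p = toy_params(matrix=matrix, baseline_edss=0, horizon=1)
        traj = mm.run_scenario(mm.ScenarioSpec("one", (("NAT", 1),)), p)
        eff = traj.effective[0][mm.Stratum.ON_TREATMENT]
        assert eff[0] == pytest.approx(0.8)
        assert eff[1] == pytest.approx(0.2)

    def test_early_switch_uses_target_dmt_from_cycle_two(self, default_params):
        traj = mm.run_scenario(mm.early_switch("GA"), default_params)
        assert traj.dmt_by_cycle == ["GA"] + ["NAT"] * 9

    def test_late_switch_segments(self, default_params):
        traj = mm.run_scenario(mm.late_switch("FTY"), default_params)
        assert traj.dmt_by_cycle == ["FTY"] * 5 + ["NAT"] * 5

    def test_horizon_mismatch_rejected(self, default_params):
        with pytest.raises(mm.ParameterValidationError, match="horizon"):
            mm.run_scenario(mm.ScenarioSpec("short", (("NAT", 3),)), default_params)

    def test_mass_conserved_and_death_monotone_all_scenarios(self, default_params):
        for name, spec in mm.build_scenario_registry().items():
            traj = mm.run_scenario(spec, default_params)
            for s in traj.states:
                assert abs(s.occupancy.sum() + s.dead_mass - 1.0) <= 1e-9, name
            dead = [s.dead_mass for s in traj.states]
            assert np.all(np.diff(dead) > 0), name  # positive mortality: strictly increasing

    def test_lower_hr_stochastically_dominates(self, default_params):
        import dataclasses

        def cum_ge(params):
            traj = mm.run_scenario(mm.continuous("NAT"), params)
            return np.stack(
                [[s.living_by_edss[e:].sum() for e in range(1, N_EDSS)] for s in traj.states]
            )

        prev = None
        for hr in (0.46, 0.7, 1.0):
            eff = dict(default_params.effects)
            eff["NAT"] = dataclasses.replace(eff["NAT"], hr_cdp6=hr)
            cur = cum_ge(dataclasses.replace(default_params, effects=eff))
            if prev is not None:
                assert np.all(prev <= cur + 1e-12)  # lower hr never increases mass above any threshold
            prev = cur

    def test_trajectory_export_is_tidy(self, nat_outcomes):
        df = nat_outcomes.trajectory.to_frame()
        assert set(df.columns) == {
            "cycle", "stratum", "edss", "occupancy", "effective_occupancy", "dead_mass"
        }
        assert len(df) == 10 * 2 * N_EDSS
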