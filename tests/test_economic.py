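import numpy as np
import pytest

import msmarkov as mm
from conftest import manual_trajectory, toy_params
from msmarkov.params import N_EDSS


class TestDiscountFactor:
    def test_zero_rate(self):
        assert mm.discount_factor(1, 0.0) == 1.0

    def test_end_of_cycle(self):
        assert mm.discount_factor(1, 0.03, timing="end_cycle") == pytest.approx(1 / 1.03)

    def test_mid_cycle(self):
        assert mm.discount_factor(3, 0.03) == pytest.approx(1.03**-2.5)

    def test_matches_closed_form_tightly(self):
        for k in range(1, 31):
            assert abs(mm.discount_factor(k, 0.03) - (1.03) ** -(k - 0.5)) <= 1e-12
            assert abs(mm.discount_factor(k, 0.05, "end_cycle") - 1.05**-k) <= 1e-12

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError, match="rate"):
            mm.discount_factor(1, -0.01)

    def test_cycle_zero_rejected(self):
        with pytest.raises(ValueError, match="cycle"):
            mm.discount_factor(0, 0.03)


class TestComputeCosts:
    def test_single_cycle_additivity(self):
        C, D = 1234.0, 5678.0
        p = toy_params(horizon=1, state_cost=C, dmt_cost=D)
        res = mm.evaluate_scenario(p, mm.ScenarioSpec("one", (("NAT", 1),)))
        assert res.economic.total_costs == pytest.approx(C + D)
        assert res.economic.dmt_costs == pytest.approx(D)
        assert res.economic.disease_management_costs == pytest.approx(C)

    def test_all_dead_cohort_costs_nothing(self):
        occ = np.zeros((2, N_EDSS))
        traj = manual_trajectory([occ, occ], scenario=mm.ScenarioSpec("one", (("NAT", 1),)))
        p = toy_params(horizon=1, state_cost=100.0, dmt_cost=100.0)
        econ = mm.compute_costs(traj, p.costs, traj.scenario, np.zeros((1, 3)), p.config)
        assert econ.total_costs == 0.0
        assert econ.relapse_costs == 0.0

    def test_accounting_identities_all_scenarios(self, default_params):
        for name in mm.build_scenario_registry():
            e = mm.evaluate_scenario(default_params, name).economic
            assert e.total_costs == pytest.approx(
                e.disease_management_costs + e.dmt_costs, abs=1e-6
            )
            assert e.disease_management_costs == pytest.approx(
                e.direct_medical_non_dmt + e.direct_non_medical + e.indirect_costs, abs=1e-6
            )
            # relapse costs excluded from the aggregate
            assert e.total_costs < e.total_costs + e.relapse_costs or e.relapse_costs == 0

    def test_relapse_costs_linear_in_unit_price(self):
        import dataclasses

        p1 = toy_params(relapse_cost=(100.0, 200.0, 300.0))
        costs2 = mm.CostInputs(
            state_costs=p1.costs.state_costs,
            dmt_annual_cost=p1.costs.dmt_annual_cost,
            relapse_cost_by_severity=2 * np.asarray(p1.costs.relapse_cost_by_severity),
        )
        p2 = dataclasses.replace(p1, costs=costs2)
        e1 = mm.evaluate_scenario(p1, mm.continuous("NAT")).economic
        e2 = mm.evaluate_scenario(p2, mm.continuous("NAT")).economic
        assert e2.relapse_costs == pytest.approx(2 * e1.relapse_costs)

    def test_dmt_cost_weakly_lower_for_late_switch_with_cheaper_initial(self, default_params):
        nat = mm.evaluate_scenario(default_params, "continuous:NAT").economic
        for d in ("GA", "TER", "DMF", "FTY"):
            assert default_params.costs.dmt_annual_cost[d] < default_params.costs.dmt_annual_cost["NAT"]
            late = mm.evaluate_scenario(default_params, f"late_switch:{d}").economic
            assert late.dmt_costs <= nat.dmt_costs + 1e-9

    def test_missing_price_raises(self, default_params):
        import dataclasses

        scenario = mm.continuous("NAT")
        traj = mm.run_scenario(scenario, default_params)
        costs = mm.CostInputs(
            state_costs=default_params.costs.state_costs,
            dmt_annual_cost={"GA": 1.0, "TER": 1.0, "DMF": 1.0, "FTY": 1.0, "NAT": 1.0},
            relapse_cost_by_severity=default_params.costs.relapse_cost_by_severity,
        )
        scenario_bad = mm.ScenarioSpec("x", (("XXX", 10),))
        with pytest.raises(mm.MissingInputError, match="XXX"):
            mm.compute_costs(traj, costs, scenario_bad, np.zeros((10, 3)), default_params.config)

    def test_person_years_annualization_switch(self):
        p = toy_params(state_cost=100.0, q_death=0.02, annualization="person_years")
        res = mm.evaluate_scenario(p, mm.continuous("NAT"))
        # flat 100-euro state cost per living person-year: exactly 100 under PY divisor
        assert res.economic.disease_management_costs == pytest.approx(100.0)


class TestEmployment:
    def test_flat_rate(self):
        occ = np.zeros((2, N_EDSS))
        occ[0, 2] = 1.0
        traj = manual_trajectory([occ, occ])
        p = toy_params(employment=0.8)
        np.testing.assert_allclose(mm.compute_employment(traj, p.productivity), 0.8)

    def test_half_dead_cohort(self):
        occ = np.zeros((2, N_EDSS))
        occ[0, 2] = 0.5  # other half of the cohort is dead
        traj = manual_trajectory([occ, occ])
        p = toy_params(employment=0.8)
        np.testing.assert_allclose(mm.compute_employment(traj, p.productivity), 0.4)

    def test_path_non_increasing_on_default_bundle(self, nat_outcomes):
        path = nat_outcomes.economic.employment_path
        assert np.all(np.diff(path) <= 1e-12)
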