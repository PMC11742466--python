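import numpy as np
import pytest

import msmarkov as mm
from conftest import manual_trajectory, toy_params
from msmarkov.params import N_EDSS


def _const_occupancy(edss_to_mass: dict[int, float], cycles: int = 10, stratum=1):
    occ = np.zeros((2, N_EDSS))
    for e, m in edss_to_mass.items():
        occ[stratum, e] = m
    return manual_trajectory([occ.copy() for _ in range(cycles + 1)])


class TestTimeInStates:
    def test_single_state_cohort(self):
        traj = _const_occupancy({2: 1.0})
        tis = mm.time_in_states(traj)
        assert tis["mild"] == pytest.approx(100.0)

    def test_symmetric_split(self):
        traj = _const_occupancy({2: 0.5, 5: 0.5})
        tis = mm.time_in_states(traj)
        assert tis["mild"] == pytest.approx(50.0)
        assert tis["walking_aid"] == pytest.approx(50.0)

    def test_sums_to_hundred_on_default_run(self, nat_outcomes):
        assert sum(nat_outcomes.clinical.time_in_band.values()) == pytest.approx(100.0, abs=0.01)

    def test_bands_must_partition(self):
        with pytest.raises(mm.ParameterValidationError, match="partition"):
            mm.DisabilityBands({"a": (0, 3), "b": (5, 9)})


class TestFinalDistribution:
    def test_degenerate_no_death(self):
        traj = _const_occupancy({0: 1.0})
        fin = mm.final_distribution(traj)
        assert fin["mild"] == pytest.approx(100.0)
        assert fin["dead"] == pytest.approx(0.0)

    def test_percentages_are_of_full_cohort(self, nat_outcomes):
        c = nat_outcomes.clinical
        total = sum(c.final_distribution.values()) + c.dead_fraction
        assert total == pytest.approx(100.0, abs=1e-9)

    def test_ge7_is_wheelchair_plus_bedridden(self, nat_outcomes):
        c = nat_outcomes.clinical
        assert c.prop_reaching_ge7 == pytest.approx(
            c.final_distribution["wheelchair"] + c.final_distribution["bedridden"], abs=1e-12
        )


class TestMeanEdss:
    def test_point_mass(self):
        traj = _const_occupancy({3: 1.0})
        assert mm.mean_edss(traj)[0] == pytest.approx(3.0)

    def test_symmetry(self):
        traj = _const_occupancy({2: 0.5, 4: 0.5})
        np.testing.assert_allclose(mm.mean_edss(traj), 3.0)

    def test_baseline_default_distribution(self, nat_outcomes):
        assert nat_outcomes.clinical.mean_edss_path[0] == pytest.approx(2.3, abs=1e-9)


class TestExpectedRelapses:
    def test_one_year_bsc_at_natural_rate(self):
        p = toy_params(horizon=1)
        occ = np.zeros((2, N_EDSS))
        occ[mm.Stratum.BSC, 2] = 1.0
        traj = manual_trajectory([occ, occ], scenario=mm.ScenarioSpec("one", (("NAT", 1),)))
        rel = mm.expected_relapses(traj, p)
        assert rel.total == pytest.approx(0.7)

    def test_zero_treatment_multiplier(self):
        p = toy_params(horizon=1, arr_on=0.0)
        traj = mm.run_scenario(mm.ScenarioSpec("one", (("NAT", 1),)), p)
        rel = mm.expected_relapses(traj, p)
        assert rel.total == pytest.approx(0.0)

    def test_zero_reference_arr_with_nonzero_on_treatment_errors(self):
        p = toy_params(horizon=1, arr_natural=0.0, arr_on=0.3)
        with pytest.raises(mm.ParameterValidationError, match="reference ARR"):
            p.relapse_multiplier("NAT")

    def test_severity_split_applied(self, default_params, nat_outcomes):
        c = nat_outcomes.clinical
        split = default_params.relapse.severity_split
        assert c.relapses_by_severity["mild"] == pytest.approx(c.relapses_total * split[0])
        assert sum(c.relapses_by_severity.values()) == pytest.approx(c.relapses_total)


class TestDalys:
    def test_zero_weights_zero_deaths(self):
        p = toy_params()
        traj = mm.run_scenario(mm.continuous("NAT"), p)
        d = mm.compute_dalys(traj, p.weights, p.mortality, 0.7)
        assert d.yld == 0.0 and d.yll == 0.0 and d.daly == 0.0

    def test_constant_weight_closed_form(self):
        w = 0.25
        p = toy_params(weights=np.full(N_EDSS, w), horizon=7)
        traj = mm.run_scenario(mm.ScenarioSpec("c", (("NAT", 7),)), p)
        d = mm.compute_dalys(traj, p.weights, p.mortality, 0.7)
        assert d.yld == pytest.approx(w * 7)

    def test_unit_multiplier_gives_zero_yll(self):
        # with no MS excess mortality, no deaths are MS-attributable
        p = toy_params(q_death=0.01)
        traj = mm.run_scenario(mm.continuous("NAT"), p)
        d = mm.compute_dalys(traj, p.weights, p.mortality, 0.7, attribution="excess")
        assert traj.states[-1].dead_mass > 0
        assert d.yll == 0.0

    def test_all_deaths_attribution_switch(self):
        p = toy_params(q_death=0.01)
        traj = mm.run_scenario(mm.continuous("NAT"), p)
        d = mm.compute_dalys(traj, p.weights, p.mortality, 0.7, attribution="all_deaths")
        assert d.yll > 0

    def test_daly_is_exact_sum(self, nat_outcomes):
        c = nat_outcomes.clinical
        assert c.daly == c.yld + c.yll

    def test_yld_monotone_in_weights(self, default_params):
        traj = mm.run_scenario(mm.continuous("NAT"), default_params)
        base = mm.compute_dalys(traj, default_params.weights, default_params.mortality, 0.7)
        heavier = mm.DisabilityWeights(
            np.minimum(1.0, default_params.weights.w_by_edss + 0.05)
        )
        up = mm.compute_dalys(traj, heavier, default_params.mortality, 0.7)
        assert up.yld > base.yld
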