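import numpy as np
import pytest

import msmarkov as mm
from msmarkov.params import ALL_COST_SUBCATS, N_EDSS


@pytest.fixture(scope="session")
def default_params():
    return mm.default_parameters()


@pytest.fixture(scope="session")
def synth_params():
    return mm.generate_parameters(mm.SyntheticSpec(seed=7))


@pytest.fixture(scope="session")
def nat_outcomes(default_params):
    return mm.evaluate_scenario(default_params, "continuous:NAT")


def toy_params(
    matrix=None,
    hr=1.0,
    p_discontinue=0.0,
    arr_natural=0.7,
    arr_on=None,
    q_death=0.0,
    multipliers=None,
    weights=None,
    state_cost=0.0,
    dmt_cost=0.0,
    relapse_cost=(0.0, 0.0, 0.0),
    employment=0.8,
    baseline_edss=2,
    baseline_dist=None,
    horizon=10,
    discount=0.0,
    **config_over,
):
    """Minimal controllable bundle: one DMT ("NAT"), flat tables, optional
    identity dynamics and zero mortality."""
    if matrix is None:
        matrix = np.eye(N_EDSS)
    if baseline_dist is None:
        baseline_dist = np.zeros(N_EDSS)
        baseline_dist[baseline_edss] = 1.0
    arr = np.full(N_EDSS, arr_natural, dtype=float)
    ref_arr = float(baseline_dist @ arr)
    if arr_on is None:
        arr_on = ref_arr  # relapse multiplier 1
    ages = np.arange(28.0, 121.0)
    state_costs = {c: np.zeros(N_EDSS) for c in ALL_COST_SUBCATS}
    state_costs["inpatient"] = np.full(N_EDSS, float(state_cost))
    return mm.ModelParameters(
        natural_history=mm.NaturalHistoryMatrix(matrix),
        relapse=mm.RelapseModel(arr_by_edss=arr, severity_split=np.array([0.4, 0.45, 0.15])),
        effects={
            "NAT": mm.TreatmentEffect(
                "NAT", hr_cdp6=hr, arr_on_treatment=arr_on, p_discontinue=p_discontinue
            )
        },
        mortality=mm.MortalityModel(
            ages=ages,
            q_female=np.full(ages.size, q_death),
            q_male=np.full(ages.size, q_death),
            le_female=np.full(ages.size, 40.0),
            le_male=np.full(ages.size, 38.0),
            multiplier_by_edss=np.ones(N_EDSS) if multipliers is None else np.asarray(multipliers, float),
        ),
        weights=mm.DisabilityWeights(np.zeros(N_EDSS) if weights is None else np.asarray(weights, float)),
        costs=mm.CostInputs(
            state_costs=state_costs,
            dmt_annual_cost={"NAT": float(dmt_cost)},
            relapse_cost_by_severity=np.asarray(relapse_cost, float),
        ),
        productivity=mm.ProductivityInputs(
            employment_rate=np.full(N_EDSS, employment),
            fulltime_rate=np.full(N_EDSS, 0.5),
            invalidity_pension_rate=np.full(N_EDSS, 0.1),
            informal_care_days=np.full(N_EDSS, 10.0),
        ),
        baseline=mm.BaselineCohort(
            edss_distribution=baseline_dist, mean_age=36.0, female_fraction=0.7
        ),
        config=mm.SimulationConfig(
            horizon_years=horizon, discount_rate_costs=discount, **config_over
        ),
    )


def manual_trajectory(occupancies, ages=None, scenario=None, dmts=None):
    """Build a trajectory from explicit (2, 10) boundary occupancies (no deaths)."""
    states = [
        mm.CohortState(occupancy=np.asarray(o, float), dead_mass=1.0 - float(np.sum(o)),
                       cohort_age=36.0 + t)
        for t, o in enumerate(occupancies)
    ]
    T = len(states) - 1
    scenario = scenario or mm.ScenarioSpec("toy", (("NAT", T),))
    dead0 = states[0].dead_mass
    return mm.CohortTrajectory(
        scenario=scenario,
        states=states,
        effective=[0.5 * (states[k].occupancy + states[k + 1].occupancy) for k in range(T)],
        effective_dead=np.array(
            [0.5 * (states[k].dead_mass + states[k + 1].dead_mass) for k in range(T)]
        ),
        deaths_by_edss=np.stack(
            [
                (states[k].living_by_edss - states[k + 1].living_by_edss).clip(min=0.0)
                for k in range(T)
            ]
        )
        if dead0 == 0.0
        else np.zeros((T, N_EDSS)),
        ages_at_cycle_start=np.array([36.0 + k for k in range(T)]),
        dmt_by_cycle=dmts or ["NAT"] * T,
    )
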