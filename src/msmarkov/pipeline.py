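"""One-call evaluation of a scenario: trajectory + clinical + economic outcomes."""

from __future__ import annotations

from dataclasses import dataclass

from .clinical import ClinicalOutcomes, compute_clinical, expected_relapses
from .economic import EconomicOutcomes, compute_costs, compute_employment
from .engine import CohortTrajectory, run_scenario
from .params import ModelParameters
from .scenarios import ScenarioSpec, build_scenario_registry


@dataclass(frozen=True)
class ScenarioOutcomes:
    scenario: ScenarioSpec
    trajectory: CohortTrajectory
    clinical: ClinicalOutcomes
    economic: EconomicOutcomes


def evaluate_scenario(
    params: ModelParameters, scenario: ScenarioSpec | str
) -> ScenarioOutcomes:
    """Run one scenario end to end on a validated parameter bundle.

    Accepts either a ScenarioSpec or a registry name such as
    "continuous:NAT", "early_switch:GA", "late_switch:FTY".
    """
    if isinstance(scenario, str):
        registry = build_scenario_registry(params.config.horizon_years)
        if scenario not in registry:
            raise KeyError(
                f"unknown scenario '{scenario}'; known: {sorted(registry)}"
            )
        scenario = registry[scenario]
    traj = run_scenario(scenario, params)
    clin = compute_clinical(traj, params)
    relapses = expected_relapses(traj, params)
    econ = compute_costs(traj, params.costs, scenario, relapses.by_cycle, params.config)
    econ = EconomicOutcomes(
        **{
            **econ.__dict__,
            "employment_path": compute_employment(traj, params.productivity),
        }
    )
    return ScenarioOutcomes(scenario=scenario, trajectory=traj, clinical=clin, economic=econ)
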