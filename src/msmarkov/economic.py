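"""Economic outcomes: discounted cost categories and the employment path.

Accounting identities (enforced by construction):

    total costs              = disease management costs + DMT costs
    disease management costs = direct medical (non-DMT) + direct non-medical
                               + indirect costs

Relapse-management costs are reported strictly separately and never added to
the aggregated categories, because the per-EDSS cost blocks from the
societal cost-of-illness sources may already partially capture them.

All costs are discounted (mid-cycle timing by default, matching the
half-cycle correction) and reported as mean annual euros per patient:
summed discounted cost divided by the horizon in years.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .engine import CohortTrajectory, Stratum
from .params import (
    ALL_COST_SUBCATS,
    DIRECT_MEDICAL_SUBCATS,
    DIRECT_NON_MEDICAL_SUBCATS,
    INDIRECT_SUBCATS,
    SEVERITIES,
    CostInputs,
    MissingInputError,
    ParameterValidationError,
    ProductivityInputs,
    SimulationConfig,
)
from .scenarios import ScenarioSpec


def discount_factor(cycle: int, rate: float, timing: str = "mid_cycle") -> float:
    """Discount factor for costs accrued in cycle k (1-based).

    "mid_cycle" discounts at (1+r)^-(k-0.5) (costs accrue mid-cycle, matching
    the half-cycle correction); "end_cycle" uses (1+r)^-k.
    """
    if cycle < 1:
        raise ValueError(f"cycle must be >= 1, got {cycle}")
    if rate < 0:
        raise ValueError(f"discount rate must be >= 0, got {rate}")
    if timing == "mid_cycle":
        return float((1.0 + rate) ** -(cycle - 0.5))
    if timing == "end_cycle":
        return float((1.0 + rate) ** -cycle)
    raise ValueError(f"unknown discount timing '{timing}'")


@dataclass(frozen=True)
class EconomicOutcomes:
    """Table-2-style cost outputs for one scenario, mean annual euros per patient."""

    total_costs: float
    dmt_costs: float
    disease_management_costs: float
    direct_medical_non_dmt: float
    direct_non_medical: float
    indirect_costs: float
    relapse_costs: float  # reported separately, excluded from total_costs
    subcategories: dict[str, float] = field(default_factory=dict)
    employment_path: np.ndarray | None = None


def compute_costs(
    traj: CohortTrajectory,
    costs: CostInputs,
    scenario: ScenarioSpec,
    relapses_by_cycle: np.ndarray,
    config: SimulationConfig,
) -> EconomicOutcomes:
    """Discounted per-category costs for one trajectory.

    DMT acquisition cost accrues on the half-cycle-corrected on-treatment
    mass (discontinuers pay half a year in their exit cycle); every per-EDSS
    state-cost subcategory accrues on effective living occupancy of both
    strata; relapse cost applies the per-event price by severity to the
    expected relapse counts per cycle.
    """
    T = traj.horizon
    relapses_by_cycle = np.asarray(relapses_by_cycle, dtype=float)
    if relapses_by_cycle.shape != (T, 3):
        raise ParameterValidationError(
            f"relapses_by_cycle: expected shape ({T}, 3), got {relapses_by_cycle.shape}"
        )
    dmt_seq = scenario.dmt_sequence()
    for d in set(dmt_seq):
        if d not in costs.dmt_annual_cost:
            raise MissingInputError(f"costs.dmt_annual_cost: missing price for DMT '{d}'")

    df = np.array(
        [discount_factor(k, config.discount_rate_costs, config.discount_timing) for k in range(1, T + 1)]
    )

    sub = {c: 0.0 for c in ALL_COST_SUBCATS}
    dmt_total = 0.0
    relapse_total = 0.0
    living_py_discounted = 0.0
    for k in range(1, T + 1):
        eff = traj.effective[k - 1]
        living = eff.sum(axis=0)
        on_mass = float(eff[Stratum.ON_TREATMENT].sum())
        d = df[k - 1]
        for c in ALL_COST_SUBCATS:
            sub[c] += d * float(living @ costs.state_costs[c])
        dmt_total += d * costs.dmt_annual_cost[dmt_seq[k - 1]] * on_mass
        relapse_total += d * float(relapses_by_cycle[k - 1] @ costs.relapse_cost_by_severity)
        living_py_discounted += d * float(living.sum())

    if config.annualization == "horizon":
        divisor = float(T)
    else:
        divisor = living_py_discounted
    sub = {c: v / divisor for c, v in sub.items()}
    dmt_total /= divisor
    relapse_total /= divisor

    direct_medical = sum(sub[c] for c in DIRECT_MEDICAL_SUBCATS)
    direct_non_medical = sum(sub[c] for c in DIRECT_NON_MEDICAL_SUBCATS)
    indirect = sum(sub[c] for c in INDIRECT_SUBCATS)
    disease_management = direct_medical + direct_non_medical + indirect

    return EconomicOutcomes(
        total_costs=disease_management + dmt_total,
        dmt_costs=dmt_total,
        disease_management_costs=disease_management,
        direct_medical_non_dmt=direct_medical,
        direct_non_medical=direct_non_medical,
        indirect_costs=indirect,
        relapse_costs=relapse_total,
        subcategories=sub,
    )


def compute_employment(
    traj: CohortTrajectory, productivity: ProductivityInputs
) -> np.ndarray:
    """Proportion of the initial cohort employed at each cycle boundary.

    Dead mass contributes zero (the denominator is the initial cohort), so
    the path reflects both EDSS-related workforce exit and mortality.
    """
    rate = productivity.employment_rate
    return np.array([float(s.living_by_edss @ rate) for s in traj.states])


def relapse_severity_split_costs(
    relapses_by_severity: dict[str, float], costs: CostInputs
) -> dict[str, float]:
    """Undiscounted relapse-management cost per severity class (convenience for figure data)."""
    unit = dict(zip(SEVERITIES, costs.relapse_cost_by_severity))
    return {s: relapses_by_severity[s] * unit[s] for s in SEVERITIES}
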