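"""Cohort propagation: treatment-adjusted transition rows and annual-cycle stepping.

The living cohort is tracked over two strata -- ON_TREATMENT and BSC (best
supportive care after discontinuation) -- each spanning EDSS 0..9, plus one
absorbing death state.  One annual cycle applies, in this fixed order:

1. all-cause death, competing first from every living state, with the
   EDSS-specific excess-mortality multiplier;
2. EDSS transitions among survivors: on-treatment mass uses hazard-ratio-
   adjusted rows, BSC mass the natural-history rows;
3. the stopping rule: on-treatment mass arriving at or above the EDSS
   threshold (default 7) moves to BSC;
4. random discontinuation: a fraction p_discontinue of the remaining
   on-treatment mass moves to BSC;
5. the cohort ages by one year.

Discontinuation is absorbing: BSC mass never returns to treatment, including
at switch-scenario segment boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum

import numpy as np
import pandas as pd

from .params import (
    N_EDSS,
    ModelParameters,
    MortalityModel,
    ParameterValidationError,
)
from .scenarios import ScenarioSpec


class Stratum(IntEnum):
    ON_TREATMENT = 0
    BSC = 1


class InfeasibleAdjustmentError(ParameterValidationError):
    """Hazard-ratio adjustment would drive a stay-probability below zero."""


def adjust_progression(
    natural_row: np.ndarray,
    source_edss: int,
    hr: float,
    method: str = "probability",
) -> np.ndarray:
    """Apply a disability-progression hazard ratio to one transition row.

    Every worsening entry (target EDSS > source) is scaled; the freed (or
    required) mass is added to (taken from) the stay-probability.  Improving
    entries are never adjusted: the hazard ratio is defined for disability
    accumulation only.

    method "probability" multiplies each one-cycle worsening probability by
    hr directly; "rate" converts each worsening probability to a constant
    hazard, scales it, and converts back (p' = 1 - (1-p)^hr).
    """
    row = np.asarray(natural_row, dtype=float)
    if row.ndim != 1:
        raise ParameterValidationError("adjust_progression: expected a 1-D probability row")
    if hr <= 0:
        raise ParameterValidationError(f"adjust_progression: hr must be > 0, got {hr}")
    if abs(row.sum() - 1.0) > 1e-9:
        raise ParameterValidationError("adjust_progression: row does not sum to 1")
    out = row.copy()
    worsen = np.arange(row.size) > source_edss
    if method == "probability":
        out[worsen] = row[worsen] * hr
    elif method == "rate":
        out[worsen] = 1.0 - (1.0 - row[worsen]) ** hr
    else:
        raise ValueError(f"unknown hr application method '{method}'")
    delta = row[worsen].sum() - out[worsen].sum()
    stay = row[source_edss] + delta
    if stay < -1e-12:
        raise InfeasibleAdjustmentError(
            f"infeasible adjustment: stay-probability {stay:.4g} < 0 at EDSS {source_edss} (hr={hr})"
        )
    out[source_edss] = max(stay, 0.0)
    return out


def build_treated_matrix(
    natural: np.ndarray, hr: float, method: str = "probability"
) -> np.ndarray:
    """Hazard-ratio-adjusted transition matrix (row-wise adjust_progression)."""
    return np.stack(
        [adjust_progression(natural[i], i, hr, method) for i in range(natural.shape[0])]
    )


def death_probability(
    edss: int, age: float, mortality: MortalityModel, female_fraction: float
) -> float:
    """Annual death probability: EDSS multiplier times the sex-mixed all-cause rate, capped at 1."""
    q = mortality.q_general(age, female_fraction)
    return min(1.0, float(mortality.multiplier_by_edss[edss]) * q)


@dataclass(frozen=True, eq=False)
class CohortState:
    """Cohort occupancy over (stratum x EDSS) plus the absorbing death mass."""

    occupancy: np.ndarray  # shape (2, 10): [ON_TREATMENT, BSC] x EDSS
    dead_mass: float
    cohort_age: float

    def __post_init__(self) -> None:
        occ = np.asarray(self.occupancy, dtype=float)
        if occ.shape != (2, N_EDSS):
            raise ParameterValidationError(f"CohortState: occupancy shape {occ.shape} != (2, 10)")
        if np.any(occ < -1e-12) or self.dead_mass < -1e-12:
            raise ParameterValidationError("CohortState: negative mass")
        total = occ.sum() + self.dead_mass
        if abs(total - 1.0) > 1e-9:
            raise ParameterValidationError(f"CohortState: total mass {total:.12g} != 1")
        occ = np.clip(occ, 0.0, None)
        occ.setflags(write=False)
        object.__setattr__(self, "occupancy", occ)
        object.__setattr__(self, "dead_mass", max(float(self.dead_mass), 0.0))

    @property
    def living_mass(self) -> float:
        return float(self.occupancy.sum())

    @property
    def living_by_edss(self) -> np.ndarray:
        return self.occupancy.sum(axis=0)


def _step(
    state: CohortState,
    treated_matrix: np.ndarray,
    natural_matrix: np.ndarray,
    p_discontinue: float,
    params: ModelParameters,
) -> tuple[CohortState, np.ndarray]:
    """One annual cycle; returns the new state and deaths by source EDSS."""
    occ = state.occupancy
    q_mix = params.mortality.q_general(state.cohort_age, params.baseline.female_fraction)
    q_death = np.minimum(1.0, params.mortality.multiplier_by_edss * q_mix)

    deaths_by_stratum = occ * q_death[None, :]
    deaths_by_edss = deaths_by_stratum.sum(axis=0)
    surv = occ - deaths_by_stratum

    on = surv[Stratum.ON_TREATMENT] @ treated_matrix
    bsc = surv[Stratum.BSC] @ natural_matrix

    thr = params.config.stop_threshold_edss
    if thr < N_EDSS:
        bsc = bsc.copy()
        bsc[thr:] += on[thr:]
        on = on.copy()
        on[thr:] = 0.0

    bsc = bsc + on * p_discontinue
    on = on * (1.0 - p_discontinue)

    new = CohortState(
        occupancy=np.stack([on, bsc]),
        dead_mass=state.dead_mass + deaths_by_edss.sum(),
        cohort_age=state.cohort_age + 1.0,
    )
    return new, deaths_by_edss


def step_cohort(state: CohortState, dmt: str, params: ModelParameters) -> CohortState:
    """Advance the cohort one annual cycle under the given DMT."""
    if dmt not in params.effects:
        raise ParameterValidationError(f"unknown DMT '{dmt}'")
    eff = params.effects[dmt]
    treated = build_treated_matrix(
        params.natural_history.p, eff.hr_cdp6, params.config.hr_application
    )
    new, _ = _step(state, treated, params.natural_history.p, eff.p_discontinue, params)
    return new


@dataclass(eq=False)
class CohortTrajectory:
    """Per-cycle occupancy with half-cycle-corrected effective occupancy.

    states has length T+1 (cycle boundaries t=0..T); effective[k-1] is the
    effective (trapezoid) occupancy attributed to cycle k, shape (2, 10);
    deaths_by_edss[k-1] are the deaths occurring during cycle k by the EDSS
    level occupied when death competed; ages_at_cycle_start[k-1] is the
    cohort age at which cycle k's mortality was evaluated.
    """

    scenario: ScenarioSpec
    states: list[CohortState]
    effective: list[np.ndarray]
    effective_dead: np.ndarray
    deaths_by_edss: np.ndarray
    ages_at_cycle_start: np.ndarray
    dmt_by_cycle: list[str] = field(default_factory=list)

    @property
    def horizon(self) -> int:
        return len(self.states) - 1

    @property
    def effective_living(self) -> np.ndarray:
        """(T, 10) half-cycle-corrected living occupancy summed over strata."""
        return np.stack([e.sum(axis=0) for e in self.effective])

    @property
    def effective_on_treatment(self) -> np.ndarray:
        """(T,) half-cycle-corrected on-treatment living mass per cycle."""
        return np.array([e[Stratum.ON_TREATMENT].sum() for e in self.effective])

    def to_frame(self) -> pd.DataFrame:
        """Tidy export: cycle, stratum, edss, occupancy, effective_occupancy, dead_mass."""
        rows = []
        for k in range(1, self.horizon + 1):
            end = self.states[k]
            for s in Stratum:
                for e in range(N_EDSS):
                    rows.append(
                        {
                            "cycle": k,
                            "stratum": s.name,
                            "edss": e,
                            "occupancy": end.occupancy[s, e],
                            "effective_occupancy": self.effective[k - 1][s, e],
                            "dead_mass": end.dead_mass,
                        }
                    )
        return pd.DataFrame(rows)


def initial_state(params: ModelParameters) -> CohortState:
    """Whole cohort on treatment at entry, distributed per the baseline EDSS mix."""
    occ = np.zeros((2, N_EDSS))
    occ[Stratum.ON_TREATMENT] = params.baseline.edss_distribution
    return CohortState(occupancy=occ, dead_mass=0.0, cohort_age=params.baseline.mean_age)


def run_scenario(scenario: ScenarioSpec, params: ModelParameters) -> CohortTrajectory:
    """Propagate the cohort through all cycles of a treatment-sequencing scenario.

    At a segment boundary the surviving on-treatment mass switches to the next
    DMT's efficacy, relapse, discontinuation, and cost parameters; BSC mass
    stays in BSC.  Effective occupancies are the arithmetic mean of
    cycle-start and cycle-end occupancy (trapezoid rule) when the half-cycle
    correction is enabled, else the cycle-end occupancy.
    """
    horizon = params.config.horizon_years
    if scenario.total_years != horizon:
        raise ParameterValidationError(
            f"scenario '{scenario.name}' spans {scenario.total_years} years, "
            f"config horizon is {horizon}"
        )
    for d, _ in scenario.segments:
        if d not in params.effects:
            raise ParameterValidationError(f"scenario '{scenario.name}': unknown DMT '{d}'")

    natural = params.natural_history.p
    treated_cache = {
        d: build_treated_matrix(natural, params.effects[d].hr_cdp6, params.config.hr_application)
        for d in {d for d, _ in scenario.segments}
    }

    state = initial_state(params)
    states = [state]
    effective: list[np.ndarray] = []
    effective_dead = np.empty(horizon)
    deaths = np.empty((horizon, N_EDSS))
    ages = np.empty(horizon)
    dmt_seq = scenario.dmt_sequence()

    for k, dmt in enumerate(dmt_seq, start=1):
        ages[k - 1] = state.cohort_age
        new, d_by_edss = _step(
            state,
            treated_cache[dmt],
            natural,
            params.effects[dmt].p_discontinue,
            params,
        )
        if params.config.half_cycle_correction:
            effective.append(0.5 * (state.occupancy + new.occupancy))
            effective_dead[k - 1] = 0.5 * (state.dead_mass + new.dead_mass)
        else:
            effective.append(new.occupancy.copy())
            effective_dead[k - 1] = new.dead_mass
        deaths[k - 1] = d_by_edss
        states.append(new)
        state = new

    return CohortTrajectory(
        scenario=scenario,
        states=states,
        effective=effective,
        effective_dead=effective_dead,
        deaths_by_edss=deaths,
        ages_at_cycle_start=ages,
        dmt_by_cycle=dmt_seq,
    )
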