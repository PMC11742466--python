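"""Clinical outcomes: time in disability bands, EDSS distributions, relapses, DALYs.

Conventions mirrored from MS cost-consequence reporting:

* time-in-band percentages are of *living* patient-time (they sum to 100);
* the 10-year health-state distribution is expressed as a share of the full
  initial cohort, with the dead fraction reported separately (so the bands
  need not sum to 100);
* DALYs are undiscounted by default and split into years lived with
  disability (YLD, disability-weight-weighted living time) and years of life
  lost (YLL); by default only the MS-attributable excess share 1 - 1/multiplier
  of each death generates YLL, so a model with no excess mortality yields
  YLL = 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .engine import CohortTrajectory, Stratum
from .params import (
    N_EDSS,
    SEVERITIES,
    DisabilityWeights,
    ModelParameters,
    MortalityModel,
    ParameterValidationError,
)

DEFAULT_BANDS = {
    "mild": (0, 3),
    "walking_aid": (4, 6),
    "wheelchair": (7, 7),
    "bedridden": (8, 9),
}


@dataclass(frozen=True)
class DisabilityBands:
    """Named contiguous EDSS ranges that must exactly partition 0..9."""

    bands: dict[str, tuple[int, int]] = field(default_factory=lambda: dict(DEFAULT_BANDS))

    def __post_init__(self) -> None:
        covered = sorted(
            e for lo, hi in self.bands.values() for e in range(lo, hi + 1)
        )
        if covered != list(range(N_EDSS)):
            raise ParameterValidationError("DisabilityBands: bands must partition EDSS 0-9 exactly")

    def mask(self, name: str) -> np.ndarray:
        lo, hi = self.bands[name]
        m = np.zeros(N_EDSS, dtype=bool)
        m[lo : hi + 1] = True
        return m


@dataclass(frozen=True)
class RelapseOutcome:
    """Expected relapse events per patient, total and by severity, undiscounted."""

    total: float
    by_severity: dict[str, float]
    by_cycle: np.ndarray  # (T, 3) expected events per severity per cycle
    by_cycle_total: np.ndarray  # (T,)


@dataclass(frozen=True)
class DalyResult:
    yld: float
    yll: float

    @property
    def daly(self) -> float:
        return self.yld + self.yll


@dataclass(frozen=True)
class ClinicalOutcomes:
    """All Table-1-style clinical outputs for one scenario."""

    time_in_band: dict[str, float]  # % of living patient-time
    final_distribution: dict[str, float]  # % of initial cohort per band
    dead_fraction: float  # % of initial cohort dead at horizon
    prop_reaching_ge7: float  # % of initial cohort at EDSS >= 7 at horizon
    mean_edss_path: np.ndarray  # (T+1,) mean EDSS among alive at cycle boundaries
    relapses_total: float
    relapses_by_severity: dict[str, float]
    yld: float
    yll: float
    daly: float


def time_in_states(
    traj: CohortTrajectory, bands: DisabilityBands | None = None
) -> dict[str, float]:
    """Percentage of living patient-time spent in each disability band."""
    bands = bands or DisabilityBands()
    living = traj.effective_living  # (T, 10)
    denom = living.sum()
    return {
        name: float(living[:, bands.mask(name)].sum() / denom * 100.0)
        for name in bands.bands
    }


def final_distribution(
    traj: CohortTrajectory, bands: DisabilityBands | None = None
) -> dict[str, float]:
    """Band shares of the full initial cohort at the horizon.

    The returned mapping includes a "dead" entry; band percentages therefore
    need not sum to 100 on their own.
    """
    bands = bands or DisabilityBands()
    end = traj.states[-1]
    living = end.living_by_edss
    out = {name: float(living[bands.mask(name)].sum() * 100.0) for name in bands.bands}
    out["dead"] = float(end.dead_mass * 100.0)
    return out


def mean_edss(traj: CohortTrajectory) -> np.ndarray:
    """Occupancy-weighted mean EDSS among the living at each cycle boundary.

    Cycles with no living mass are reported as NaN (missing).
    """
    levels = np.arange(N_EDSS, dtype=float)
    out = np.empty(len(traj.states))
    for t, s in enumerate(traj.states):
        alive = s.living_mass
        out[t] = (s.living_by_edss @ levels) / alive if alive > 0 else np.nan
    return out


def expected_relapses(traj: CohortTrajectory, params: ModelParameters) -> RelapseOutcome:
    """Expected relapses per patient over the horizon.

    On-treatment mass relapses at the state-specific natural rate scaled by
    the DMT's relapse multiplier (anchored to the published on-treatment ARR
    at the baseline EDSS mix); BSC mass relapses at the natural rate.
    """
    arr = params.relapse.arr_by_edss
    T = traj.horizon
    by_cycle_total = np.empty(T)
    for k in range(1, T + 1):
        mult = params.relapse_multiplier(traj.dmt_by_cycle[k - 1])
        eff = traj.effective[k - 1]
        on = float(eff[Stratum.ON_TREATMENT] @ arr) * mult
        bsc = float(eff[Stratum.BSC] @ arr)
        by_cycle_total[k - 1] = on + bsc
    split = params.relapse.severity_split
    by_cycle = by_cycle_total[:, None] * split[None, :]
    total = float(by_cycle_total.sum())
    return RelapseOutcome(
        total=total,
        by_severity={s: float(total * split[i]) for i, s in enumerate(SEVERITIES)},
        by_cycle=by_cycle,
        by_cycle_total=by_cycle_total,
    )


def compute_dalys(
    traj: CohortTrajectory,
    weights: DisabilityWeights,
    mortality: MortalityModel,
    female_fraction: float,
    attribution: str = "excess",
    discount_rate: float = 0.0,
) -> DalyResult:
    """Years lived with disability, years of life lost, and their sum.

    YLD sums disability-weighted effective living occupancy over cycles.
    YLL multiplies each cycle's deaths by the residual life expectancy at the
    age of death and, under "excess" attribution, by the MS-attributable
    share max(0, 1 - 1/multiplier) of the EDSS state the death occurred from.
    """
    if attribution not in ("excess", "all_deaths"):
        raise ParameterValidationError(f"unknown YLL attribution '{attribution}'")
    w = weights.w_by_edss
    T = traj.horizon
    df = (
        np.ones(T)
        if discount_rate == 0.0
        else (1.0 + discount_rate) ** -(np.arange(1, T + 1) - 0.5)
    )
    yld = float((traj.effective_living @ w) @ df)

    if attribution == "excess":
        share = np.maximum(0.0, 1.0 - 1.0 / mortality.multiplier_by_edss)
    else:
        share = np.ones(N_EDSS)
    yll = 0.0
    for k in range(T):
        deaths = traj.deaths_by_edss[k]
        if deaths.sum() <= 0:
            continue
        le = mortality.life_expectancy(traj.ages_at_cycle_start[k], female_fraction)
        yll += float((deaths * share).sum()) * le * df[k]
    return DalyResult(yld=yld, yll=yll)


def compute_clinical(
    traj: CohortTrajectory,
    params: ModelParameters,
    bands: DisabilityBands | None = None,
) -> ClinicalOutcomes:
    """Assemble every Table-1-style clinical outcome for one trajectory."""
    bands = bands or DisabilityBands()
    fin = final_distribution(traj, bands)
    dead = fin.pop("dead")
    relapses = expected_relapses(traj, params)
    dalys = compute_dalys(
        traj,
        params.weights,
        params.mortality,
        params.baseline.female_fraction,
        attribution=params.config.yll_attribution,
        discount_rate=params.config.discount_rate_effects,
    )
    thr_mask = np.arange(N_EDSS) >= 7
    ge7 = float(traj.states[-1].living_by_edss[thr_mask].sum() * 100.0)
    return ClinicalOutcomes(
        time_in_band=time_in_states(traj, bands),
        final_distribution=fin,
        dead_fraction=dead,
        prop_reaching_ge7=ge7,
        mean_edss_path=mean_edss(traj),
        relapses_total=relapses.total,
        relapses_by_severity=relapses.by_severity,
        yld=dalys.yld,
        yll=dalys.yll,
        daly=dalys.daly,
    )


def edss_ge7_path(traj: CohortTrajectory) -> np.ndarray:
    """Share of the initial cohort at EDSS >= 7 at each cycle boundary (percent)."""
    mask = np.arange(N_EDSS) >= 7
    return np.array([s.living_by_edss[mask].sum() * 100.0 for s in traj.states])
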