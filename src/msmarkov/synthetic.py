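"""Synthetic parameter bundles and an independent microsimulation oracle.

The generator produces structurally realistic bundles (banded row-stochastic
transition matrix with worsening mass exceeding improving mass, natural
relapse rates near 0.7 below EDSS 5 and 0.5 above, hazard ratios in
[0.45, 0.85], discontinuation in [0.08, 0.12], monotone weights, costs
increasing and employment decreasing in EDSS), deterministic given the seed.

The oracle simulates individual patients with per-year categorical draws in
exactly the cohort engine's event order (death -> transition -> stop rule ->
discontinuation) but shares no propagation code with the engine; agreement
within Monte-Carlo error is the central correctness check of the package.
Relapse counts, disability weights, and costs are accumulated as
conditional expectations given each simulated path, so standard errors
reflect path variability.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .engine import build_treated_matrix
from .params import (
    ALL_COST_SUBCATS,
    DIRECT_MEDICAL_SUBCATS,
    DIRECT_NON_MEDICAL_SUBCATS,
    INDIRECT_SUBCATS,
    N_EDSS,
    SEVERITIES,
    BaselineCohort,
    CostInputs,
    DisabilityWeights,
    ModelParameters,
    MortalityModel,
    NaturalHistoryMatrix,
    ParameterValidationError,
    ProductivityInputs,
    RelapseModel,
    SimulationConfig,
    TreatmentEffect,
    _gompertz_mortality,
)
from .pipeline import ScenarioOutcomes
from .scenarios import ScenarioSpec


@dataclass(frozen=True)
class SyntheticSpec:
    """Knobs of the synthetic world (all structural, not fitted to any source)."""

    seed: int
    progression_intensity: float = 0.12  # mean annual worsen-by-1 probability
    improvement_intensity: float = 0.05  # mean annual improve-by-1 probability
    cost_gradient: float = 1.30  # multiplicative per-EDSS cost slope
    n_dmts: int = 5

    def __post_init__(self) -> None:
        for name in ("progression_intensity", "improvement_intensity"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ParameterValidationError(f"SyntheticSpec.{name}={v}: must lie in (0, 1)")
        # the synthetic world is a progressive disease: worsening dominates.
        # With +/-20% per-row jitter, a 1.5x margin keeps that true row-wise.
        if self.improvement_intensity * 1.5 > self.progression_intensity:
            raise ParameterValidationError(
                "SyntheticSpec: improvement_intensity must be < progression_intensity / 1.5"
            )
        if self.cost_gradient <= 1.0:
            raise ParameterValidationError("SyntheticSpec.cost_gradient must be > 1")
        if self.n_dmts < 1:
            raise ParameterValidationError("SyntheticSpec.n_dmts must be >= 1")


def generate_parameters(spec: SyntheticSpec) -> ModelParameters:
    """A fully validated synthetic bundle, deterministic given spec.seed."""
    rng = np.random.default_rng(spec.seed)

    p = np.zeros((N_EDSS, N_EDSS))
    for i in range(N_EDSS):
        w1 = spec.progression_intensity * rng.uniform(0.8, 1.2) if i + 1 < N_EDSS else 0.0
        w2 = 0.25 * w1 if i + 2 < N_EDSS else 0.0
        im = spec.improvement_intensity * rng.uniform(0.8, 1.2) if i >= 1 else 0.0
        if i >= 1:
            p[i, i - 1] = im
        if i + 1 < N_EDSS:
            p[i, i + 1] = w1
        if i + 2 < N_EDSS:
            p[i, i + 2] = w2
        p[i, i] = 1.0 - p[i].sum()

    arr = np.where(np.arange(N_EDSS) <= 4, 0.7, 0.5) * rng.uniform(0.95, 1.05, N_EDSS)
    split = np.array([0.38, 0.48, 0.14]) * rng.uniform(0.9, 1.1, 3)
    split /= split.sum()

    effects = {}
    prices = {}
    for j in range(spec.n_dmts):
        d = f"DMT{j}"
        effects[d] = TreatmentEffect(
            dmt_id=d,
            hr_cdp6=float(rng.uniform(0.45, 0.85)),
            arr_on_treatment=float(rng.uniform(0.31, 0.67)),
            p_discontinue=float(rng.uniform(0.08, 0.12)),
        )
        prices[d] = float(rng.uniform(8000.0, 26000.0))

    ages, qf, qm, lf, lm = _gompertz_mortality(
        qf0=4.5e-4 * rng.uniform(0.9, 1.1),
        qm0=1.0e-3 * rng.uniform(0.9, 1.1),
    )
    mult = 1.0 + np.cumsum(rng.uniform(0.0, 0.5, N_EDSS))
    mult[0] = 1.0

    w = np.cumsum(rng.uniform(0.02, 0.10, N_EDSS))
    w = w / w[-1] * rng.uniform(0.75, 0.95)

    grad = spec.cost_gradient ** np.arange(N_EDSS)
    bases = {
        "inpatient": 900.0,
        "outpatient_stays": 110.0,
        "consultations": 800.0,
        "examinations": 300.0,
        "medication_non_dmt": 400.0,
        "community_services": 150.0,
        "investments_purchases": 180.0,
        "informal_care": 400.0,
        "short_term_absence": 500.0,
        "long_term_absence": 2500.0,
    }
    state_costs = {
        c: bases[c] * rng.uniform(0.7, 1.3) * grad for c in ALL_COST_SUBCATS
    }

    emp0 = rng.uniform(0.75, 0.85)
    emp = emp0 * np.cumprod(np.concatenate([[1.0], rng.uniform(0.75, 0.95, N_EDSS - 1)]))

    dist = np.zeros(N_EDSS)
    pr = rng.uniform(0.30, 0.45)
    from scipy.stats import binom

    dist[:7] = binom.pmf(np.arange(7), 6, pr)
    dist /= dist.sum()

    return ModelParameters(
        natural_history=NaturalHistoryMatrix(p),
        relapse=RelapseModel(arr_by_edss=arr, severity_split=split),
        effects=effects,
        mortality=MortalityModel(
            ages=ages, q_female=qf, q_male=qm, le_female=lf, le_male=lm,
            multiplier_by_edss=mult,
        ),
        weights=DisabilityWeights(w),
        costs=CostInputs(
            state_costs=state_costs,
            dmt_annual_cost=prices,
            relapse_cost_by_severity=np.array([500.0, 2500.0, 7500.0]) * rng.uniform(0.8, 1.2),
        ),
        productivity=ProductivityInputs(
            employment_rate=emp,
            fulltime_rate=emp * rng.uniform(0.5, 0.8),
            invalidity_pension_rate=np.clip((1.0 - emp) * rng.uniform(0.5, 0.9), 0.0, 1.0),
            informal_care_days=np.linspace(5.0, 300.0, N_EDSS) * rng.uniform(0.9, 1.1),
        ),
        baseline=BaselineCohort(
            edss_distribution=dist,
            mean_age=float(rng.uniform(32.0, 40.0)),
            female_fraction=float(rng.uniform(0.6, 0.8)),
        ),
        config=SimulationConfig(),
        provenance={"all": "synthetic"},
    )


# ---------------------------------------------------------------------------
# Microsimulation oracle

_BAND_RANGES = {"mild": (0, 3), "walking_aid": (4, 6), "wheelchair": (7, 7), "bedridden": (8, 9)}


@dataclass(frozen=True)
class OracleResult:
    """Monte-Carlo estimates with standard errors, keyed like cohort_summary()."""

    value: dict[str, float]
    se: dict[str, float]
    n: int = 0
    extras: dict[str, np.ndarray] = field(default_factory=dict)


def cohort_summary(outcomes: ScenarioOutcomes) -> dict[str, float]:
    """Flatten cohort-model outcomes into the scalar keys the oracle reports."""
    c, e = outcomes.clinical, outcomes.economic
    out: dict[str, float] = {}
    for b in _BAND_RANGES:
        out[f"time_in_band:{b}"] = c.time_in_band[b]
        out[f"final:{b}"] = c.final_distribution[b]
    out["final:dead"] = c.dead_fraction
    out["relapses_total"] = c.relapses_total
    for s in SEVERITIES:
        out[f"relapses:{s}"] = c.relapses_by_severity[s]
    out["yld"] = c.yld
    out["yll"] = c.yll
    out["daly"] = c.daly
    assert e.employment_path is not None
    for t, v in enumerate(e.employment_path):
        out[f"employment:{t}"] = float(v)
    out["cost_total"] = e.total_costs
    out["cost_dmt"] = e.dmt_costs
    out["cost_disease_management"] = e.disease_management_costs
    out["cost_direct_medical"] = e.direct_medical_non_dmt
    out["cost_direct_non_medical"] = e.direct_non_medical
    out["cost_indirect"] = e.indirect_costs
    out["cost_relapse"] = e.relapse_costs
    return out


def _mean_se(v: np.ndarray) -> tuple[float, float]:
    n = v.size
    return float(v.mean()), float(v.std(ddof=1) / np.sqrt(n))


def microsim_oracle(
    scenario: ScenarioSpec, params: ModelParameters, n: int, seed: int
) -> OracleResult:
    """Simulate n independent patients and report the cohort model's estimands.

    Vectorised over patients with a single seeded generator; draw order is
    cycle-major (death, transition, discontinuation uniforms for all patients
    each cycle), so results are deterministic given (seed, n).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    cfg = params.config
    if cfg.annualization != "horizon":
        raise NotImplementedError("oracle implements the horizon annualization only")
    T = cfg.horizon_years
    if scenario.total_years != T:
        raise ParameterValidationError(
            f"scenario '{scenario.name}' spans {scenario.total_years} years, horizon is {T}"
        )
    rng = np.random.default_rng(seed)
    ff = params.baseline.female_fraction
    arr = params.relapse.arr_by_edss
    split = params.relapse.severity_split
    w = params.weights.w_by_edss
    mult = params.mortality.multiplier_by_edss
    thr = cfg.stop_threshold_edss
    if cfg.yll_attribution == "excess":
        yll_share = np.maximum(0.0, 1.0 - 1.0 / mult)
    else:
        yll_share = np.ones(N_EDSS)
    unit_relapse_cost = float(split @ params.costs.relapse_cost_by_severity)

    cost_vec = {
        "dm_med": sum(params.costs.state_costs[c] for c in DIRECT_MEDICAL_SUBCATS),
        "dnm": sum(params.costs.state_costs[c] for c in DIRECT_NON_MEDICAL_SUBCATS),
        "ind": sum(params.costs.state_costs[c] for c in INDIRECT_SUBCATS),
    }

    dmt_seq = scenario.dmt_sequence()
    nat_cum = np.cumsum(params.natural_history.p, axis=1)
    treated_cum = {
        d: np.cumsum(
            build_treated_matrix(
                params.natural_history.p, params.effects[d].hr_cdp6, cfg.hr_application
            ),
            axis=1,
        )
        for d in set(dmt_seq)
    }

    edss = rng.choice(N_EDSS, size=n, p=params.baseline.edss_distribution)
    alive = np.ones(n, dtype=bool)
    on = np.ones(n, dtype=bool)
    age = params.baseline.mean_age

    band_of = np.empty(N_EDSS, dtype=int)
    band_names = list(_BAND_RANGES)
    for bi, (lo, hi) in enumerate(_BAND_RANGES.values()):
        band_of[lo : hi + 1] = bi

    living_time = np.zeros(n)
    band_time = np.zeros((n, 4))
    relapses = np.zeros(n)
    yld = np.zeros(n)
    yll = np.zeros(n)
    c_dm_med = np.zeros(n)
    c_dnm = np.zeros(n)
    c_ind = np.zeros(n)
    c_dmt = np.zeros(n)
    c_rel = np.zeros(n)
    emp_mean = np.empty(T + 1)
    emp_se = np.empty(T + 1)

    emp_rate = params.productivity.employment_rate
    ev = emp_rate[edss] * alive
    emp_mean[0], emp_se[0] = _mean_se(ev)

    w_start = 0.5 if cfg.half_cycle_correction else 0.0
    w_end = 1.0 - w_start

    r_cost = cfg.discount_rate_costs
    r_eff = cfg.discount_rate_effects
    for k in range(1, T + 1):
        dmt = dmt_seq[k - 1]
        mult_r = params.relapse_multiplier(dmt)
        price = params.costs.dmt_annual_cost[dmt]
        p_disc = params.effects[dmt].p_discontinue
        shift = k - 0.5 if cfg.discount_timing == "mid_cycle" else float(k)
        df_c = (1.0 + r_cost) ** -shift
        df_e = 1.0 if r_eff == 0.0 else (1.0 + r_eff) ** -shift

        edss0, alive0, on0 = edss.copy(), alive.copy(), on.copy()

        # 1. death competes first from every living state
        q_mix = params.mortality.q_general(age, ff)
        p_death = np.minimum(1.0, mult[edss] * q_mix)
        u1 = rng.random(n)
        dies = alive & (u1 < p_death)
        if dies.any():
            le = params.mortality.life_expectancy(age, ff)
            yll[dies] += yll_share[edss[dies]] * le * df_e
            alive[dies] = False

        # 2. survivors transition between EDSS levels
        u2 = rng.random(n)
        cumrows = np.where(on[:, None], treated_cum[dmt][edss], nat_cum[edss])
        newe = (cumrows < u2[:, None]).sum(axis=1)
        edss = np.where(alive, newe, edss)

        # 3. stop rule: on-treatment arrivals at/above the threshold exit to BSC
        if thr < N_EDSS:
            on = on & ~(alive & (edss >= thr))
        # 4. random discontinuation (absorbing)
        u3 = rng.random(n)
        on = on & ~(alive & (u3 < p_disc))

        # trapezoid accumulation of the cycle's outcomes
        a0 = alive0.astype(float) * w_start
        a1 = alive.astype(float) * w_end
        living_time += a0 + a1
        for bi in range(4):
            band_time[:, bi] += a0 * (band_of[edss0] == bi) + a1 * (band_of[edss] == bi)
        rate0 = arr[edss0] * np.where(on0, mult_r, 1.0)
        rate1 = arr[edss] * np.where(on, mult_r, 1.0)
        cyc_relapse = a0 * rate0 + a1 * rate1
        relapses += cyc_relapse
        c_rel += df_c * cyc_relapse * unit_relapse_cost
        yld += df_e * (a0 * w[edss0] + a1 * w[edss])
        c_dm_med += df_c * (a0 * cost_vec["dm_med"][edss0] + a1 * cost_vec["dm_med"][edss])
        c_dnm += df_c * (a0 * cost_vec["dnm"][edss0] + a1 * cost_vec["dnm"][edss])
        c_ind += df_c * (a0 * cost_vec["ind"][edss0] + a1 * cost_vec["ind"][edss])
        c_dmt += df_c * price * (a0 * on0 + a1 * on)

        age += 1.0
        ev = emp_rate[edss] * alive
        emp_mean[k], emp_se[k] = _mean_se(ev)

    value: dict[str, float] = {}
    se: dict[str, float] = {}

    # time-in-band is a ratio estimator; delta-method standard error
    ybar = living_time.mean()
    for bi, b in enumerate(band_names):
        R = band_time[:, bi].sum() / living_time.sum()
        z = band_time[:, bi] - R * living_time
        value[f"time_in_band:{b}"] = R * 100.0
        se[f"time_in_band:{b}"] = float(z.std(ddof=1) / np.sqrt(n) / ybar) * 100.0

    for bi, b in enumerate(band_names):
        ind = (alive & (band_of[edss] == bi)).astype(float) * 100.0
        value[f"final:{b}"], se[f"final:{b}"] = _mean_se(ind)
    dead_ind = (~alive).astype(float) * 100.0
    value["final:dead"], se["final:dead"] = _mean_se(dead_ind)

    value["relapses_total"], se["relapses_total"] = _mean_se(relapses)
    for i, s in enumerate(SEVERITIES):
        value[f"relapses:{s}"] = value["relapses_total"] * float(split[i])
        se[f"relapses:{s}"] = se["relapses_total"] * float(split[i])

    value["yld"], se["yld"] = _mean_se(yld)
    value["yll"], se["yll"] = _mean_se(yll)
    value["daly"], se["daly"] = _mean_se(yld + yll)

    for t in range(T + 1):
        value[f"employment:{t}"] = float(emp_mean[t])
        se[f"employment:{t}"] = float(emp_se[t])

    c_dm = c_dm_med + c_dnm + c_ind
    for key, v in (
        ("cost_total", (c_dm + c_dmt) / T),
        ("cost_dmt", c_dmt / T),
        ("cost_disease_management", c_dm / T),
        ("cost_direct_medical", c_dm_med / T),
        ("cost_direct_non_medical", c_dnm / T),
        ("cost_indirect", c_ind / T),
        ("cost_relapse", c_rel / T),
    ):
        value[key], se[key] = _mean_se(v)

    return OracleResult(value=value, se=se, n=n)
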