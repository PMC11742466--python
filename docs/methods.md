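# Methods

This note documents the model implemented in `msmarkov`, the choices made
where the published description of this model family is silent, and what
the synthetic-data machinery does and does not establish.

## Model structure

A discrete-time Markov cohort model with 21 states: EDSS 0–9 in an
ON_TREATMENT stratum, EDSS 0–9 in a BSC (best supportive care) stratum, and
one absorbing death state. Cycles are annual; the horizon is 10 years; a
half-cycle correction attributes to each cycle the arithmetic mean of its
start and end occupancy (trapezoid rule). The cohort enters entirely
on treatment with the baseline EDSS distribution (mass on 0–6 only) and
ages deterministically by one year per cycle.

### Within-cycle event order

The published description of this model family does not fix the order of
competing events inside a cycle. We use **death → transition → stop rule →
discontinuation**:

- death first, because all-cause mortality tables are annual probabilities
  conditional on being alive at the start of the year;
- the EDSS ≥ 7 stopping rule applies to where surviving on-treatment mass
  *lands*, so that mass changes stratum at the end of the cycle in which it
  arrives and — under half-cycle accounting — still pays half a year of that
  cycle's drug cost;
- random discontinuation applies to the mass still on treatment after the
  stop rule.

BSC is absorbing: discontinuers never re-escalate, including at the
1-year/5-year switch points of the sequencing scenarios. Only patients
still on the initial therapy switch to natalizumab.

### Treatment effect on progression

The hazard ratio for 6-month confirmed disability progression multiplies
every worsening entry of a transition row (any step size — no
step-size-specific effect is published), with the freed probability mass
returned to the diagonal. Improvement probabilities are never adjusted: the
endpoint is defined for disability *accumulation*. Direct multiplication of
one-cycle probabilities is the default because it is standard in published
MS Markov cost models and exactly reproducible; a rate-space alternative
(`p' = 1 − (1−p)^hr`, `config.hr_application = "rate"`) is provided. If an
hr > 1 would drive a stay-probability negative the adjustment raises an
`infeasible adjustment` error rather than clamping.

### Mortality

Death probability is `min(1, m(EDSS) · q_mix(age))` with
`q_mix = 0.70·q_female + 0.30·q_male`: sex is handled as a fixed mixture
weight rather than separate strata, because no sex-stratified outcome is
reported for this model family. Ages are looked up at the nearest tabulated
row, and ages outside the table raise an error (no extrapolation).

## Outcomes

- **Time in band** — half-cycle-corrected living occupancy in each band
  (mild EDSS 0–3, walking aid 4–6, wheelchair 7, bedridden 8–9) as a
  percentage of living patient-time; sums to 100.
- **10-year distribution** — band shares of the *initial* cohort, dead mass
  reported separately (so bands alone do not sum to 100). The alternative
  survivors-only convention was rejected because the published tables'
  band percentages do not sum to 100.
- **Mean EDSS** — occupancy-weighted mean among the living (conditional on
  survival) at each cycle boundary.
- **Relapses** — expected events: natural EDSS-specific rate for BSC mass;
  on-treatment mass uses a state-independent multiplier
  `ARR_on / ARR_ref`, anchored so a cohort with the baseline EDSS mix
  reproduces the published on-treatment ARR. This preserves the
  EDSS-dependence of relapse risk while using a single ARR per therapy.
  Totals are split (mild, moderate, severe) by fixed proportions
  (0.378, 0.482, 0.140) derived from the published severity breakdown.
- **DALY = YLD + YLL**, undiscounted and un-age-weighted by default
  (`config.discount_rate_effects = 0`). YLD sums disability-weighted
  effective living occupancy. YLL counts, per death, the MS-attributable
  excess share `max(0, 1 − 1/m(EDSS))` times residual life expectancy at
  the age of death; with no excess mortality (`m ≡ 1`) YLL is exactly 0,
  matching the "premature mortality" concept. An all-deaths alternative is
  `config.yll_attribution = "all_deaths"`.
- **Costs** — per cycle: drug price × effective on-treatment mass; each
  per-EDSS subcategory × effective living occupancy of both strata;
  expected relapses × per-event price by severity. Discounted at 3 %/yr at
  mid-cycle timing `(1+r)^−(k−0.5)` (consistent with the half-cycle
  correction; end-of-cycle available), summed, and divided by the horizon
  in years ("mean annual cost"; a discounted-person-years divisor is
  available as `config.annualization = "person_years"`). Indirect costs are
  taken as per-EDSS euro blocks, not recomputed from employment.
  Relapse costs are reported strictly separately because the societal
  per-EDSS cost blocks may already capture part of them.
- **Employment** — living occupancy × EDSS-specific employment rate, with
  the initial cohort as denominator (death reduces employment).

## Sensitivity analysis

One-way ±10 % multiplicative perturbations of: entry age (rounded to the
nearest integer year afterwards, since mortality is tabulated at integer
ages), female fraction (capped to [0,1]), HR 6-CDP, the on-treatment/
reference relapse-rate ratio, discontinuation probability, and annual drug
cost, per therapy. Both arms are re-run under each perturbed bundle (global
perturbation), and the incremental mean annual total cost is recorded. A
diff audit guarantees each run changes exactly one leaf of the bundle.
Because relapse costs are excluded from total costs, relapse-rate
perturbations have zero tornado range — consistent with the reported
finding that relapse-rate variation had little-to-no impact.

## Parameter provenance and placeholders

`default_parameters()` flags every field `paper` or `placeholder`:

- **Transcribed** (main-text values): entry age 36.0, 70 % female, mean
  baseline EDSS 2.3 (± 1.2), natural ARR 0.7 / 0.5 by EDSS band, NAT
  HR 0.46, TER HR 0.79, on-treatment ARR endpoints 0.31 (NAT) and 0.67
  (TER), discontinuation endpoints 8.7 % (NAT) and 11.2 % (GA), NAT price
  25,985 €, TER price 10,807 €, 3 % discounting, 10-year horizon, EDSS-7
  stopping threshold, relapse severity split.
- **Placeholders** (supplementary-table quantities not publicly printed),
  chosen once for realism and never tuned to outputs:
  - *baseline distribution*: Binomial(6, 2.3/6) over EDSS 0–6 — mean
    exactly 2.3, SD 1.19 vs the reported 1.2;
  - *transition matrix*: banded (±1, +2 moves), worsen-by-1 probability
    0.12 → 0.06 declining in EDSS, improvements 0–0.06, diagonal remainder;
  - *mortality*: Gompertz fits of German-magnitude all-cause rates
    (q(36) ≈ 4.5·10⁻⁴ female / 1.0·10⁻³ male, doubling ≈ every 7–8 years),
    with life expectancy closed from the same probabilities so the YLL
    table is self-consistent; EDSS multipliers 1.0 → 5.0;
  - *disability weights*: 0.03 → 0.90, monotone;
  - *per-EDSS cost and productivity profiles*: increasing cost/decreasing
    employment gradients at German cost-of-illness magnitudes; examinations
    and short-term absence mildly *decreasing* in EDSS (consistent with the
    published comparator ratios below 100 % for those rows);
  - *comparator prices*: anchored to the printed TER price via the
    published relative drug-cost columns (prices enter linearly):
    GA 14,000 €, DMF 6,600 €, FTY 12,000 €; comparator HRs/ARRs interpolated
    within the published ranges respecting the published efficacy ordering
    (FTY > DMF > GA > TER).

**Consequence:** relative orderings, identities, and qualitative findings
are faithful; absolute headline values that depend on the placeholder
tables differ from the published ones (the reproduction tests in
`tests/test_acceptance.py` make this visible rather than hiding it).
Replacing the flagged tables in a bundle directory with transcribed values
is the supported path to full reproduction.

## Synthetic data and the microsimulation oracle

`generate_parameters(SyntheticSpec(seed))` draws bundles with the same
structure (progressive banded matrix, monotone weights/costs/employment,
HRs in [0.45, 0.85], discontinuation in [0.08, 0.12]) — a stated world for
testing, not a fit to any real table. `SyntheticSpec` requires
progression to dominate improvement, keeping generated matrices worsening-
biased row-wise.

`microsim_oracle(scenario, params, n, seed)` simulates n independent
patients with per-year categorical draws in the engine's exact event order,
implemented separately from the engine (no shared stepping code), and
accumulates the same outcome definitions; relapses, YLD, and costs are
conditional expectations given the simulated path, so standard errors
reflect path variability. Time-in-band is a ratio estimator with a
delta-method standard error. The acceptance suite requires cohort/oracle
agreement within 3 SE on all ~34 reported outcomes for 3 seeds × 2
scenario shapes at n = 200,000.

A green oracle test establishes that the cohort engine propagates its
stated dynamics correctly; it says nothing about how well those dynamics
describe real MS cohorts (no tunnel states, no treatment waning, memoryless
transitions, annual resolution).

## Numerical notes

- Mass conservation is asserted to 1·10⁻⁹ at every cycle; validation errors
  are raised, never silently clamped.
- Bundle round-trips are exact: floats are written at shortest-round-trip
  precision and re-read with round-trip parsing.
- All randomness flows through named `numpy.random.default_rng(seed)`
  generators; the oracle is vectorised over patients with cycle-major draw
  order, so results are bit-reproducible given (seed, n).

## Known limitations

- 10-year horizon only (no lifetime extrapolation); annual cycles.
- No PML/adverse-event states, no probabilistic sensitivity analysis, no
  QALY/ICER computation (cost–consequence by design), no CPI inflation or
  market-share price weighting.
- Placeholder tables (above) limit absolute reproduction until replaced.
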