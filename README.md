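# msmarkov

A Markov cohort model for evaluating **when to start natalizumab** in highly
active relapsing–remitting multiple sclerosis, as a societal
**cost–consequence analysis**: clinical outcomes (disability trajectories,
relapses, DALYs) and economic outcomes (drug acquisition, disease-management
and relapse costs, employment) are reported side by side rather than
collapsed into a single ratio.

It is written for health-economics and neurology researchers who want a
tested, scriptable alternative to spreadsheet implementations of this model
family: every input is a validated, diffable table; every output is
reproducible; and the deterministic cohort engine is cross-checked against
an independent patient-level microsimulation.

## The model

Health states are the integer Expanded Disability Status Scale levels
EDSS 0–9 plus an absorbing all-cause death state. The cohort (entry age
36.0, 70 % female, mean EDSS 2.3, all patients starting on treatment) is
propagated in annual cycles over a 10-year horizon with a half-cycle
correction. Each cycle applies, in order:

1. **death**, competing first from every living state, with probability
   `min(1, m(EDSS) · q(age, sex-mix))` where `m` is the EDSS-specific excess
   mortality multiplier;
2. **EDSS transitions** among survivors — natural-history row
   `p(i → j)` off treatment; on treatment each worsening entry `j > i` is
   multiplied by the therapy's hazard ratio for 6-month confirmed disability
   progression (HR 6-CDP), the freed mass returned to the stay-probability;
3. **stopping rule** — on-treatment mass arriving at EDSS ≥ 7 moves to best
   supportive care (BSC);
4. **discontinuation** — a fraction `p_disc` of remaining on-treatment mass
   moves to BSC. BSC is absorbing (no re-escalation).

Relapses accrue at EDSS-specific natural rates (≈ 0.7/yr at EDSS ≤ 4,
0.5/yr above), scaled on treatment by `ARR_on / ARR_ref` anchored at the
baseline EDSS mix. DALYs = YLD (disability-weight-weighted living time) +
YLL (MS-attributable share `1 − 1/m(EDSS)` of deaths × residual life
expectancy). Costs (2024 €, societal perspective) are discounted at 3 %/yr
(mid-cycle) and annualized; total = disease-management + DMT acquisition,
with relapse costs reported separately.

Thirteen strategies are built in: continuous natalizumab (NAT), continuous
glatiramer acetate / teriflunomide / dimethyl fumarate / fingolimod, an
early switch to NAT after 1 year, and a late switch after 5 years of each
comparator.

## Worked example

```python
import msmarkov as mm

params = mm.default_parameters()            # validated input bundle
res = mm.evaluate_scenario(params, "continuous:NAT")
print(res.clinical.time_in_band["mild"])    # % of living time at EDSS 0-3
print(res.economic.total_costs)             # mean annual EUR per patient
```

Running `python examples/01_continuous_natalizumab.py` prints (abridged):

```
Time spent in health states (% of living patient-time):
  mild          77.88 %
  walking_aid   21.54 %
Mean EDSS: 2.30 at entry -> 2.75 at 10 years
Relapses per patient over 10 years: 4.32
DALY 2.02 = YLD 1.84 + YLL 0.18 (years per patient)
Discounted mean annual costs per patient (EUR):
  total                 29,568
  DMT acquisition       14,992
  disease management    14,576
```

That is: under the default bundle a continuously NAT-treated cohort spends
about 78 % of its living time with mild disability, accumulates ~4.3
relapses and ~2.0 DALYs per patient over ten years, and costs ~29.6 k€ per
patient-year, half of which is drug acquisition. The other examples compare
all 13 strategies, run the ±10 % tornado analysis, cross-check the engine
against a 200,000-patient microsimulation, and round-trip parameter bundles.

**Provenance caveat:** only the values published in the source literature's
main text are transcribed into `default_parameters()`; quantities that exist
only in unpublished supplementary tables (notably the natural-history
transition matrix and the per-EDSS cost profiles) are documented
placeholders, flagged per field in `params.provenance`. Absolute outputs
therefore indicate realistic magnitudes, not published point estimates —
see `docs/methods.md`.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the package's full pipeline from scratch: all 13 scenarios on the
default bundle (with the DALY and cost accounting identities asserted), the
one-way sensitivity analysis, and a seeded microsimulation cross-check of
the cohort engine, then writes the results JSON.

## Layout

- `src/msmarkov/params.py` — input types, validation, bundle I/O, defaults
- `src/msmarkov/engine.py` — HR adjustment, mortality, cohort propagation
- `src/msmarkov/clinical.py`, `economic.py` — outcome computation
- `src/msmarkov/sensitivity.py` — ±10 % one-way sensitivity (tornado)
- `src/msmarkov/synthetic.py` — synthetic bundles + microsimulation oracle
- `src/msmarkov/report.py` — result tables, figure data, run manifests
- `examples/` — one narrative script per capability
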