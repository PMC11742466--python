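"""Result tables, figure-data files, and run manifests.

Mirrors the conventional presentation of MS cost-consequence analyses:
clinical outcomes as absolute values for the reference scenario and
percentage-point / absolute differences for comparators; economic outcomes
as absolute euros for the reference and percent-of-reference for
comparators.  All outputs are plain CSV/JSON (UTF-8, '.' decimal separator,
no thousands separators); plotting is left to the caller.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from datetime import datetime, timezone
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .clinical import edss_ge7_path
from .economic import relapse_severity_split_costs
from .params import SEVERITIES, ModelParameters
from .pipeline import ScenarioOutcomes, evaluate_scenario
from .scenarios import ScenarioSpec, build_scenario_registry
from .sensitivity import PerturbationSpec, run_owsa

_BANDS = ("mild", "walking_aid", "wheelchair", "bedridden")


def bundle_hash(params: ModelParameters) -> str:
    """Stable sha256 of the canonical JSON form of a parameter bundle."""
    payload = json.dumps(params.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()


def make_manifest(
    params: ModelParameters, scenario_names: Sequence[str], reference: str
) -> dict:
    return {
        "tool": "msmarkov",
        "version": __version__,
        "scenarios": list(scenario_names),
        "reference": reference,
        "bundle_hash": bundle_hash(params),
        "config": dataclasses.asdict(params.config),
        "timestamp": datetime.now(timezone.utc).isoformat(),
    }


def clinical_table(
    results: dict[str, ScenarioOutcomes], reference: str
) -> pd.DataFrame:
    """Table-1-style frame: absolute values for the reference scenario and
    differences (percentage points / absolute) for every other scenario."""
    rows: dict[str, dict[str, float]] = {}

    def put(outcome: str, name: str, v: float) -> None:
        rows.setdefault(outcome, {})[name] = v

    ref = results[reference]
    for name, res in results.items():
        c = res.clinical
        is_ref = name == reference

        def rel(v: float, rv: float) -> float:
            return v if is_ref else v - rv

        for b in _BANDS:
            put(f"time_in_band:{b}", name, rel(c.time_in_band[b], ref.clinical.time_in_band[b]))
            put(
                f"final_distribution:{b}",
                name,
                rel(c.final_distribution[b], ref.clinical.final_distribution[b]),
            )
        put("prop_reaching_ge7", name, rel(c.prop_reaching_ge7, ref.clinical.prop_reaching_ge7))
        put("relapses_total", name, rel(c.relapses_total, ref.clinical.relapses_total))
        for s in SEVERITIES:
            put(
                f"relapses:{s}",
                name,
                rel(c.relapses_by_severity[s], ref.clinical.relapses_by_severity[s]),
            )
        put("daly", name, rel(c.daly, ref.clinical.daly))
        put("yld", name, rel(c.yld, ref.clinical.yld))
        put("yll", name, rel(c.yll, ref.clinical.yll))
        put("mean_edss_final", name, rel(c.mean_edss_path[-1], ref.clinical.mean_edss_path[-1]))
    return pd.DataFrame(rows).T


def economic_table(
    results: dict[str, ScenarioOutcomes], reference: str
) -> pd.DataFrame:
    """Table-2-style frame: absolute euros for the reference scenario and
    percent-of-reference for every other scenario."""
    fields = [
        ("total_costs", lambda e: e.total_costs),
        ("dmt_costs", lambda e: e.dmt_costs),
        ("disease_management_costs", lambda e: e.disease_management_costs),
        ("direct_medical_non_dmt", lambda e: e.direct_medical_non_dmt),
        ("direct_non_medical", lambda e: e.direct_non_medical),
        ("indirect_costs", lambda e: e.indirect_costs),
        ("relapse_costs", lambda e: e.relapse_costs),
    ]
    sub_names = list(results[reference].economic.subcategories)
    rows: dict[str, dict[str, float]] = {}
    ref_e = results[reference].economic
    for name, res in results.items():
        e = res.economic
        is_ref = name == reference
        for label, get in fields:
            v, rv = get(e), get(ref_e)
            rows.setdefault(label, {})[name] = v if is_ref else (v / rv * 100.0 if rv else np.nan)
        for c in sub_names:
            v, rv = e.subcategories[c], ref_e.subcategories[c]
            rows.setdefault(f"sub:{c}", {})[name] = (
                v if is_ref else (v / rv * 100.0 if rv else np.nan)
            )
    return pd.DataFrame(rows).T


def run_report(
    params: ModelParameters,
    out_dir: str | Path,
    scenario_names: Iterable[str] | None = None,
    reference: str = "continuous:NAT",
) -> dict[str, ScenarioOutcomes]:
    """Execute scenarios and write the full table/figure-data file set.

    Writes table1_clinical.csv, table2_economic.csv, per-scenario trajectory
    exports, figure-data CSVs (time-in-band shares, EDSS>=7 curve, mean-EDSS
    path, employment path, cost bars, relapse-cost bars), and manifest.json.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    registry = build_scenario_registry(params.config.horizon_years)
    names = list(scenario_names) if scenario_names is not None else list(registry)
    for n in names:
        if n not in registry:
            raise KeyError(f"unknown scenario '{n}'; known: {sorted(registry)}")
    if reference not in names:
        names = [reference] + names

    results = {n: evaluate_scenario(params, registry[n]) for n in names}

    clinical_table(results, reference).to_csv(out / "table1_clinical.csv", index_label="outcome")
    economic_table(results, reference).to_csv(out / "table2_economic.csv", index_label="outcome")

    traj_dir = out / "trajectories"
    traj_dir.mkdir(exist_ok=True)
    for n, res in results.items():
        res.trajectory.to_frame().to_csv(
            traj_dir / f"{n.replace(':', '_')}.csv", index=False
        )

    T = params.config.horizon_years
    pd.DataFrame(
        {n: {b: res.clinical.time_in_band[b] for b in _BANDS} for n, res in results.items()}
    ).T.to_csv(out / "fig_time_in_band.csv", index_label="scenario")
    pd.DataFrame(
        {n: edss_ge7_path(res.trajectory) for n, res in results.items()},
        index=pd.Index(range(T + 1), name="cycle"),
    ).to_csv(out / "fig_edss_ge7_path.csv")
    pd.DataFrame(
        {n: res.clinical.mean_edss_path for n, res in results.items()},
        index=pd.Index(range(T + 1), name="cycle"),
    ).to_csv(out / "fig_mean_edss_path.csv")
    pd.DataFrame(
        {n: res.economic.employment_path for n, res in results.items()},
        index=pd.Index(range(T + 1), name="cycle"),
    ).to_csv(out / "fig_employment_path.csv")
    pd.DataFrame(
        {
            n: {
                "total": res.economic.total_costs,
                "dmt": res.economic.dmt_costs,
                "disease_management": res.economic.disease_management_costs,
                "direct_medical_non_dmt": res.economic.direct_medical_non_dmt,
                "direct_non_medical": res.economic.direct_non_medical,
                "indirect": res.economic.indirect_costs,
            }
            for n, res in results.items()
        }
    ).T.to_csv(out / "fig_cost_bars.csv", index_label="scenario")
    pd.DataFrame(
        {
            n: {
                "relapse_costs_annual_discounted": res.economic.relapse_costs,
                **{
                    f"undiscounted:{s}": v
                    for s, v in relapse_severity_split_costs(
                        res.clinical.relapses_by_severity, params.costs
                    ).items()
                },
            }
            for n, res in results.items()
        }
    ).T.to_csv(out / "fig_relapse_costs.csv", index_label="scenario")

    (out / "manifest.json").write_text(
        json.dumps(make_manifest(params, names, reference), indent=2)
    )
    return results


def run_owsa_report(
    params: ModelParameters,
    out_dir: str | Path,
    reference: str = "continuous:NAT",
    comparator: str = "continuous:GA",
    perturbations: Sequence[PerturbationSpec] | None = None,
) -> pd.DataFrame:
    """Run the one-way sensitivity analysis and write a tornado-ready CSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    registry = build_scenario_registry(params.config.horizon_years)
    entries = run_owsa(registry[reference], registry[comparator], params, perturbations)
    df = pd.DataFrame(
        [
            {
                "parameter_id": e.parameter_id,
                "low": e.incremental_cost_low,
                "high": e.incremental_cost_high,
                "base": e.base_incremental_cost,
                "range": e.range,
            }
            for e in entries
        ]
    )
    df.to_csv(out / f"tornado_{comparator.replace(':', '_')}.csv", index=False)
    return df
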