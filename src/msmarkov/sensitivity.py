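"""One-way deterministic sensitivity analysis (tornado data).

Each perturbation multiplies exactly one base value by 0.9 or 1.1 (global
perturbation: both arms are re-run under the changed bundle), and the
incremental mean annual total cost (reference minus comparator) is recorded.
Entries are sorted by tornado range, descending.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .params import ModelParameters, ParameterValidationError
from .pipeline import evaluate_scenario
from .scenarios import ScenarioSpec

FACTORS = (0.9, 1.1)

#: DMT-specific perturbable families; "arr_hr" scales the on-treatment/reference
#: relapse-rate ratio (implemented by scaling the on-treatment ARR).
DMT_FAMILIES = ("hr_cdp6", "arr_hr", "p_discontinue", "dmt_cost")


@dataclass(frozen=True)
class PerturbationSpec:
    """A single multiplicative +/-10% perturbation of one base parameter.

    parameter_id is "age", "female_fraction", or "<family>:<DMT>" with family
    one of hr_cdp6 / arr_hr / p_discontinue / dmt_cost.
    """

    parameter_id: str
    factor: float

    def __post_init__(self) -> None:
        if self.factor not in FACTORS:
            raise ParameterValidationError(
                f"perturbation factor must be one of {FACTORS}, got {self.factor}"
            )

    @property
    def direction(self) -> str:
        return "+10%" if self.factor > 1 else "-10%"


@dataclass(frozen=True)
class TornadoEntry:
    parameter_id: str
    incremental_cost_low: float  # under the x0.9 perturbation
    incremental_cost_high: float  # under the x1.1 perturbation
    base_incremental_cost: float

    @property
    def range(self) -> float:
        return abs(self.incremental_cost_high - self.incremental_cost_low)


def apply_perturbation(params: ModelParameters, spec: PerturbationSpec) -> ModelParameters:
    """Rebuild the bundle with the single perturbed value.

    Entry age is rounded to the nearest integer year after scaling (mortality
    is looked up at integer ages); proportions are capped to [0, 1].
    """
    d = params.to_dict()
    pid, f = spec.parameter_id, spec.factor
    if pid == "age":
        d["baseline"]["mean_age"] = float(round(d["baseline"]["mean_age"] * f))
    elif pid == "female_fraction":
        d["baseline"]["female_fraction"] = min(1.0, max(0.0, d["baseline"]["female_fraction"] * f))
    elif ":" in pid:
        family, dmt = pid.split(":", 1)
        if family == "dmt_cost":
            prices = d["costs"]["dmt_annual_cost"]
            if dmt not in prices:
                raise ParameterValidationError(f"perturbation of undefined parameter '{pid}'")
            prices[dmt] = prices[dmt] * f
        else:
            if dmt not in d["effects"]:
                raise ParameterValidationError(f"perturbation of undefined parameter '{pid}'")
            e = d["effects"][dmt]
            if family == "hr_cdp6":
                e["hr_cdp6"] = e["hr_cdp6"] * f
            elif family == "arr_hr":
                e["arr_on_treatment"] = e["arr_on_treatment"] * f
            elif family == "p_discontinue":
                e["p_discontinue"] = min(math.nextafter(1.0, 0.0), max(0.0, e["p_discontinue"] * f))
            else:
                raise ParameterValidationError(f"perturbation of undefined parameter '{pid}'")
    else:
        raise ParameterValidationError(f"perturbation of undefined parameter '{pid}'")
    return ModelParameters.from_dict(d)


def param_diff(a: ModelParameters, b: ModelParameters) -> list[str]:
    """Paths of every leaf value that differs between two bundles (audit helper)."""

    def walk(x, y, path: str, out: list[str]) -> None:
        if isinstance(x, dict):
            for k in x:
                walk(x[k], y[k], f"{path}.{k}" if path else str(k), out)
        elif isinstance(x, list):
            if np.array_equal(np.asarray(x, dtype=object), np.asarray(y, dtype=object)):
                return
            out.append(path)
        else:
            if x != y and not (x is None and y is None):
                out.append(path)

    out: list[str] = []
    walk(a.to_dict(), b.to_dict(), "", out)
    return out


def default_perturbations(dmts: Iterable[str]) -> list[PerturbationSpec]:
    """The standard perturbation set: age, sex mix, and the four DMT-specific
    families (6-CDP HR, ARR ratio, discontinuation, acquisition cost) for each
    listed DMT, each in both directions."""
    specs: list[PerturbationSpec] = []
    for pid in ("age", "female_fraction"):
        for f in FACTORS:
            specs.append(PerturbationSpec(pid, f))
    for dmt in dmts:
        for family in DMT_FAMILIES:
            for f in FACTORS:
                specs.append(PerturbationSpec(f"{family}:{dmt}", f))
    return specs


def _incremental_cost(
    reference: ScenarioSpec, comparator: ScenarioSpec, params: ModelParameters
) -> float:
    ref = evaluate_scenario(params, reference).economic.total_costs
    cmp_ = evaluate_scenario(params, comparator).economic.total_costs
    return ref - cmp_


def run_owsa(
    reference: ScenarioSpec,
    comparator: ScenarioSpec,
    params: ModelParameters,
    perturbations: Sequence[PerturbationSpec] | None = None,
) -> list[TornadoEntry]:
    """One-way sensitivity analysis of the incremental mean annual total cost.

    With perturbations=None the standard set over the DMTs appearing in the
    two scenarios is used; an empty sequence returns only the base case (a
    single entry with low = high = base).  Results are deterministic.
    """
    if perturbations is None:
        dmts = sorted(
            {d for d, _ in reference.segments} | {d for d, _ in comparator.segments}
        )
        perturbations = default_perturbations(dmts)

    base = _incremental_cost(reference, comparator, params)
    if not perturbations:
        return [TornadoEntry("base_case", base, base, base)]

    by_param: dict[str, dict[float, float]] = {}
    for spec in perturbations:
        perturbed = apply_perturbation(params, spec)
        by_param.setdefault(spec.parameter_id, {})[spec.factor] = _incremental_cost(
            reference, comparator, perturbed
        )
    entries = [
        TornadoEntry(
            parameter_id=pid,
            incremental_cost_low=vals.get(0.9, base),
            incremental_cost_high=vals.get(1.1, base),
            base_incremental_cost=base,
        )
        for pid, vals in by_param.items()
    ]
    entries.sort(key=lambda e: (-e.range, e.parameter_id))
    return entries
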