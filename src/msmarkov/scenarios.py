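"""Treatment-sequencing scenarios: ordered (DMT, duration) segments and the standard registry."""

from __future__ import annotations

from dataclasses import dataclass

from .params import ParameterValidationError


@dataclass(frozen=True)
class ScenarioSpec:
    """An ordered sequence of (dmt_id, duration_years) segments.

    Durations are positive integer years; the engine checks that they sum to
    the configured horizon at run time.
    """

    name: str
    segments: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        segments = tuple((str(d), int(y)) for d, y in self.segments)
        if not segments:
            raise ParameterValidationError(f"scenario '{self.name}': no segments")
        for d, y in segments:
            if y < 1:
                raise ParameterValidationError(
                    f"scenario '{self.name}': segment ({d}, {y}) has non-positive duration"
                )
        object.__setattr__(self, "segments", segments)

    @property
    def total_years(self) -> int:
        return sum(y for _, y in self.segments)

    def dmt_at_cycle(self, cycle: int) -> str:
        """DMT active during cycle k (1-based)."""
        if not (1 <= cycle <= self.total_years):
            raise ValueError(f"cycle {cycle} outside scenario '{self.name}'")
        acc = 0
        for d, y in self.segments:
            acc += y
            if cycle <= acc:
                return d
        raise AssertionError("unreachable")

    def dmt_sequence(self) -> list[str]:
        """Active DMT for every cycle 1..total_years."""
        out: list[str] = []
        for d, y in self.segments:
            out.extend([d] * y)
        return out


def continuous(dmt: str, horizon: int = 10) -> ScenarioSpec:
    return ScenarioSpec(f"continuous:{dmt}", ((dmt, horizon),))


def early_switch(dmt: str, to: str = "NAT", horizon: int = 10) -> ScenarioSpec:
    """One year of the initial DMT, then escalation to the target (default NAT)."""
    return ScenarioSpec(f"early_switch:{dmt}", ((dmt, 1), (to, horizon - 1)))


def late_switch(dmt: str, to: str = "NAT", horizon: int = 10) -> ScenarioSpec:
    """Five years of the initial DMT, then escalation to the target (default NAT)."""
    return ScenarioSpec(f"late_switch:{dmt}", ((dmt, 5), (to, horizon - 5)))


def build_scenario_registry(horizon: int = 10) -> dict[str, ScenarioSpec]:
    """The 13 standard scenario columns: continuous NAT, 4 early switches to
    NAT, 4 late switches to NAT, and 4 continuous comparators."""
    comparators = ("GA", "TER", "DMF", "FTY")
    reg: dict[str, ScenarioSpec] = {}
    for d in ("NAT",) + comparators:
        s = continuous(d, horizon)
        reg[s.name] = s
    for d in comparators:
        s = early_switch(d, horizon=horizon)
        reg[s.name] = s
    for d in comparators:
        s = late_switch(d, horizon=horizon)
        reg[s.name] = s
    return reg
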