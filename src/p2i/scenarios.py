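"""Config-driven funding-scenario runner.

Seven built-in fund scenarios span annual disbursements from $1M (passive
coordination of R&D, no project funding) to a $500M global fund.  For
operational scenarios a financing strategy — a mix of archetypes entering
per year — is scaled so its steady-state annual cost fits the fund size,
then run through the planner/engine over the modelling horizon.

Strategy templates are illustrative and overridable: "quick wins" leans on
repurposed drugs (short, cheap, high-probability paths), "innovation" on
novel vaccines, chemical entities, biologics and platforms, and "mixed"
blends the two equally.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import yaml

from .engine import PortfolioTimeline, round_launches_for_report
from .params import ParameterSet
from .planner import (EntryRow, EntrySchedule, SteadyState, plan_prospective,
                      schedule_to_projects, steady_state)

__all__ = [
    "STRATEGY_TEMPLATES",
    "ScenarioConfig",
    "ScenarioReport",
    "builtin_scenarios",
    "fit_portfolio_to_budget",
    "run_scenario",
    "load_scenario_config",
]

#: Illustrative archetype mixes (entrant weights; each sums to 1).
STRATEGY_TEMPLATES: dict[str, dict[str, float]] = {
    "quick_wins": {
        "repurposed_simple": 0.7,
        "repurposed_complex": 0.2,
        "diagnostic_assay": 0.1,
    },
    "innovation": {
        "vaccine_complex": 0.2,
        "nce_innovative": 0.3,
        "nce_complex": 0.2,
        "biologic_complex": 0.2,
        "diagnostic_platform": 0.1,
    },
}
STRATEGY_TEMPLATES["mixed"] = {
    aid: 0.5 * STRATEGY_TEMPLATES["quick_wins"].get(aid, 0.0)
    + 0.5 * STRATEGY_TEMPLATES["innovation"].get(aid, 0.0)
    for aid in sorted(set(STRATEGY_TEMPLATES["quick_wins"]) | set(STRATEGY_TEMPLATES["innovation"]))
}


@dataclass(frozen=True)
class ScenarioConfig:
    """One funding scenario: fund size, strategy and horizon.

    Non-operational scenarios fund coordination/prioritization only, no
    development projects.
    """

    name: str
    annual_fund_size: float  # $M per year
    strategy: str | Mapping[str, float] = "mixed"
    horizon: tuple[int, int] | None = None  # default: parameter-set horizon
    operational: bool = True
    description: str = ""

    def __post_init__(self) -> None:
        if self.annual_fund_size <= 0:
            raise ValueError(f"annual fund size must be > 0, got {self.annual_fund_size}")

    def mix(self) -> dict[str, float]:
        if isinstance(self.strategy, str):
            try:
                weights = STRATEGY_TEMPLATES[self.strategy]
            except KeyError:
                raise ValueError(
                    f"unknown strategy {self.strategy!r}; templates: "
                    + ", ".join(STRATEGY_TEMPLATES)
                )
        else:
            weights = dict(self.strategy)
        total = sum(weights.values())
        if total <= 0:
            raise ValueError("strategy mix weights must sum to a positive value")
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"explicit mix weights must sum to 1, got {total}")
        return {aid: w for aid, w in weights.items() if w > 0}


@dataclass(frozen=True)
class ScenarioReport:
    """Outputs of one scenario run."""

    config: ScenarioConfig
    entrants_per_year: Mapping[str, float]  # new projects initiated per year, by archetype
    steady: SteadyState | None
    timeline: PortfolioTimeline
    horizon: tuple[int, int]

    @property
    def years(self) -> range:
        return range(self.horizon[0], self.horizon[1] + 1)

    @property
    def new_projects_per_year(self) -> float:
        return sum(self.entrants_per_year.values())

    @property
    def steady_state_portfolio_size(self) -> float:
        return self.steady.total_projects if self.steady is not None else 0.0

    @property
    def expected_launches(self) -> float:
        """Cumulative expected launches by the end of the horizon (floating point)."""
        return self.timeline.cumulative_launches_by(self.horizon[1])

    @property
    def expected_launches_rounded(self) -> int:
        return round_launches_for_report(self.expected_launches)

    @property
    def budget_trace(self) -> dict[int, float]:
        """Annual expected disbursement ($M) over the horizon."""
        if not self.config.operational:
            return {y: self.config.annual_fund_size for y in self.years}
        return {y: self.timeline.yearly_cost.get(y, 0.0) for y in self.years}

    def launches_by_year(self) -> dict[int, float]:
        return {y: self.timeline.yearly_launches.get(y, 0.0) for y in self.years}

    def to_text(self) -> str:
        lines = [
            f"Scenario: {self.config.name}",
            f"  annual fund size: {self.config.annual_fund_size:.1f} $M",
            f"  operational: {self.config.operational}",
            f"  horizon: {self.horizon[0]}-{self.horizon[1]}",
        ]
        if self.config.operational:
            strategy = (self.config.strategy if isinstance(self.config.strategy, str)
                        else "custom mix")
            lines.append(f"  strategy: {strategy}")
            lines.append(f"  new projects initiated per year: {self.new_projects_per_year:.2f}")
            for aid, n in sorted(self.entrants_per_year.items()):
                lines.append(f"    {aid}: {n:.2f}")
            lines.append(f"  steady-state portfolio size: {self.steady_state_portfolio_size:.1f}")
            assert self.steady is not None
            lines.append(f"  steady-state annual cost: {self.steady.annual_cost:.1f} $M")
            lines.append(
                f"  expected launches by {self.horizon[1]}: "
                f"{self.expected_launches:.2f} (rounded: {self.expected_launches_rounded})"
            )
        else:
            lines.append("  coordination/prioritization only; no projects funded")
        lines.append("  annual budget trace ($M):")
        for y, v in self.budget_trace.items():
            lines.append(f"    {y}: {v:.2f}")
        return "\n".join(lines)


def builtin_scenarios(ps: ParameterSet | None = None) -> list[ScenarioConfig]:
    """The seven built-in fund scenarios ($1M to $500M per year)."""
    specs = [
        (1, 1.0, False, "up to $1M/yr to support passive coordination of R&D"),
        (2, 5.0, False, "up to $5M/yr to support prioritization of R&D"),
        (3, 15.0, True, "a small fund of approx. $15M/yr"),
        (4, 50.0, True, "a PDP-sized fund of approx. $50M/yr"),
        (5, 100.0, True, "a medium-sized fund of approx. $100M/yr"),
        (6, 300.0, True, "a large fund of approx. $300M/yr"),
        (7, 500.0, True, "a global fund of approx. $500M/yr"),
    ]
    return [
        ScenarioConfig(name=f"scenario-{num}", annual_fund_size=size,
                       operational=op, description=desc)
        for num, size, op, desc in specs
    ]


def fit_portfolio_to_budget(cfg: ScenarioConfig, ps: ParameterSet) -> EntrySchedule:
    """Scale the strategy mix so steady-state annual cost fills the fund.

    The per-archetype annual entrant rates are the mix weights times the
    largest common factor keeping the steady-state annual cost within the
    annual fund size.  Costs are linear in entrants, so the factor is simply
    fund size / unit-mix steady-state cost.  Returns one entry row per
    archetype per horizon year.
    """
    if not cfg.operational:
        raise ValueError(f"{cfg.name}: non-operational scenarios fund no projects")
    rates = _fit_rates(cfg, ps)
    start, end = cfg.horizon if cfg.horizon is not None else (ps.horizon_start, ps.horizon_end)
    rows = [
        EntryRow(archetype=aid, entry_phase=ps.archetype(aid).entry_phase_default,
                 year=float(year), entrants=rate)
        for year in range(start, end + 1)
        for aid, rate in sorted(rates.items())
        if rate > 0
    ]
    return EntrySchedule(tuple(rows))


def _fit_rates(cfg: ScenarioConfig, ps: ParameterSet) -> dict[str, float]:
    mix = cfg.mix()
    unit_cost = steady_state(mix, ps).annual_cost  # $M/yr for 1 entrant/yr split by mix
    if unit_cost <= 0:
        return {aid: 0.0 for aid in mix}
    factor = cfg.annual_fund_size / unit_cost
    return {aid: w * factor for aid, w in mix.items()}


def run_scenario(cfg: ScenarioConfig, ps: ParameterSet) -> ScenarioReport:
    """Fit a scenario's portfolio to its budget and run it over the horizon."""
    horizon = cfg.horizon if cfg.horizon is not None else (ps.horizon_start, ps.horizon_end)
    if cfg.horizon is not None:
        from dataclasses import replace
        ps = replace(ps, horizon_start=horizon[0], horizon_end=horizon[1])
    if not cfg.operational:
        return ScenarioReport(config=cfg, entrants_per_year={}, steady=None,
                              timeline=PortfolioTimeline(), horizon=horizon)
    rates = _fit_rates(cfg, ps)
    schedule = fit_portfolio_to_budget(cfg, ps)
    timeline = plan_prospective(schedule, ps)
    return ScenarioReport(config=cfg, entrants_per_year=rates,
                          steady=steady_state(rates, ps),
                          timeline=timeline, horizon=horizon)


def load_scenario_config(path: str | Path) -> ScenarioConfig:
    """Read a scenario config from YAML or JSON.

    Keys: name, annual_fund_size ($M/yr), strategy (template name or
    explicit archetype->weight mapping), horizon ([start, end], optional),
    operational (default true).
    """
    p = Path(path)
    data = (json.loads(p.read_text()) if p.suffix.lower() == ".json"
            else yaml.safe_load(p.read_text()))
    if not isinstance(data, dict):
        raise ValueError(f"{path}: scenario config must be a mapping")
    horizon = data.get("horizon")
    return ScenarioConfig(
        name=str(data.get("name", p.stem)),
        annual_fund_size=float(data["annual_fund_size"]),
        strategy=data.get("strategy", "mixed"),
        horizon=tuple(int(v) for v in horizon) if horizon else None,
        operational=bool(data.get("operational", True)),
        description=str(data.get("description", "")),
    )
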