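"""Prospective and retrospective portfolio planning.

Prospective (funding-based) planning answers "if I fund this many entrants
per year, what do I get?": an entry schedule is expanded into projects and
aggregated by the engine.  Retrospective (outcome-based) planning inverts the
attrition chain: given a target count at a phase (or at launch) by a given
year, it computes how many candidates must enter, and when, via the
reciprocal of the cumulative probability of success.

Steady-state sizing applies flow equilibrium (Little's law): with a constant
entry rate, the expected number of candidates simultaneously active in phase
k is the entry rate into that phase times its duration, and the annual cost
is the entry rate into each phase times its cost.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .engine import PortfolioTimeline, Project, aggregate
from .params import N_PHASES, ParameterSet, cumulative_pos

__all__ = [
    "LAUNCH",
    "EntryRow",
    "EntrySchedule",
    "OutcomeTarget",
    "PlanSolution",
    "SteadyState",
    "InfeasibleTargetError",
    "plan_prospective",
    "schedule_to_projects",
    "solve_entrants",
    "steady_state",
    "annual_budget",
]

#: Sentinel target phase meaning "product launch" (past phase 3).
LAUNCH = "launch"


class InfeasibleTargetError(ValueError):
    """The outcome target cannot be met within the modelling horizon."""


@dataclass(frozen=True)
class EntryRow:
    """One schedule row: entrants of one archetype in one calendar year."""

    archetype: str
    entry_phase: int
    year: float
    entrants: float  # expected candidates entering that year; fractional allowed

    def __post_init__(self) -> None:
        if self.entrants < 0:
            raise ValueError(f"entrants must be >= 0, got {self.entrants}")


@dataclass(frozen=True)
class EntrySchedule:
    rows: tuple[EntryRow, ...] = ()

    def __iter__(self):
        return iter(self.rows)

    def __len__(self) -> int:
        return len(self.rows)


@dataclass(frozen=True)
class OutcomeTarget:
    """An outcome-based goal: reach ``target_count`` at ``target_phase`` by ``by_year``.

    ``target_phase`` is a phase ordinal 0..3 or :data:`LAUNCH`.
    """

    archetype: str
    target_phase: int | str
    target_count: float
    by_year: float
    entry_phase: int | None = None  # default: archetype's earliest applicable phase

    def __post_init__(self) -> None:
        if self.target_count <= 0:
            raise ValueError(f"target_count must be > 0, got {self.target_count}")
        if self.target_phase != LAUNCH and not (0 <= int(self.target_phase) < N_PHASES):
            raise ValueError(f"target_phase must be 0..3 or {LAUNCH!r}, got {self.target_phase}")


@dataclass(frozen=True)
class PlanSolution:
    """Entrants needed (expected-value and integerized) and when to start."""

    archetype: str
    entry_phase: int
    entrants: float  # exact fractional entrants
    entrants_ceil: int  # integerized (ceiling) variant
    entry_year: float
    target: OutcomeTarget

    def as_schedule(self, integerize: bool = False) -> EntrySchedule:
        n = float(self.entrants_ceil) if integerize else self.entrants
        return EntrySchedule((EntryRow(self.archetype, self.entry_phase, self.entry_year, n),))


@dataclass(frozen=True)
class SteadyState:
    """Flow-equilibrium portfolio size and budget for constant annual entrants."""

    occupancy: Mapping[str, tuple[float, float, float, float]]  # archetype -> per-phase
    annual_cost: float  # $M per year
    annual_cost_by_archetype: Mapping[str, float]

    @property
    def occupancy_by_phase(self) -> tuple[float, float, float, float]:
        totals = [0.0] * N_PHASES
        for occ in self.occupancy.values():
            for k in range(N_PHASES):
                totals[k] += occ[k]
        return tuple(totals)  # type: ignore[return-value]

    @property
    def total_projects(self) -> float:
        return sum(self.occupancy_by_phase)


def schedule_to_projects(schedule: EntrySchedule | Sequence[EntryRow]) -> list[Project]:
    """Expand schedule rows into engine projects (multiplicity = entrants)."""
    return [
        Project(archetype=r.archetype, entry_phase=r.entry_phase,
                entry_time=float(r.year), multiplicity=r.entrants)
        for r in schedule
        if r.entrants > 0
    ]


def plan_prospective(schedule: EntrySchedule | Sequence[EntryRow],
                     ps: ParameterSet) -> PortfolioTimeline:
    """Run a funding-based plan: expand the schedule and aggregate timelines."""
    return aggregate(schedule_to_projects(schedule), ps)


def _chain_end(target_phase: int | str) -> int:
    """Last phase ordinal traversed before the target is reached."""
    return N_PHASES - 1 if target_phase == LAUNCH else int(target_phase) - 1


def solve_entrants(target: OutcomeTarget, ps: ParameterSet) -> PlanSolution:
    """Invert the attrition chain for an outcome-based target.

    The entrants needed equal the target count divided by the cumulative
    probability of success from the entry phase through the phase preceding
    the target (the full chain for a launch target); the entry year is the
    target year minus the traversed cycle time.
    """
    arch = ps.archetype(target.archetype)
    entry = arch.entry_phase_default if target.entry_phase is None else target.entry_phase
    if entry < arch.entry_phase_default:
        raise ValueError(
            f"{target.archetype}: entry phase {entry} precedes earliest applicable phase"
        )
    last = _chain_end(target.target_phase)
    if last < entry - 1:
        raise InfeasibleTargetError(
            f"target phase {target.target_phase} precedes entry phase {entry}"
        )
    p = cumulative_pos(ps, target.archetype, entry, last)
    entrants = target.target_count / p
    lead_time = sum(arch.phases[k].duration for k in range(entry, last + 1))
    entry_year = target.by_year - lead_time
    if entry_year < ps.horizon_start:
        raise InfeasibleTargetError(
            f"reaching {target.target_count} at {target.target_phase!r} by "
            f"{target.by_year} requires entry in {entry_year:.2f}, before the "
            f"horizon start {ps.horizon_start}"
        )
    return PlanSolution(
        archetype=target.archetype,
        entry_phase=entry,
        entrants=entrants,
        entrants_ceil=math.ceil(entrants - 1e-12),
        entry_year=entry_year,
        target=target,
    )


def steady_state(entrants_per_year: Mapping[str, float], ps: ParameterSet) -> SteadyState:
    """Flow-equilibrium occupancy and annual cost for constant entry rates.

    Entrants enter each archetype at its earliest applicable phase.  At
    equilibrium the entry rate into phase k is the entrant rate times the
    cumulative probability of success over earlier phases, the occupancy of
    phase k is that rate times the phase duration, and the annual cost is
    that rate times the phase cost.
    """
    occupancy: dict[str, tuple[float, float, float, float]] = {}
    cost_by_arch: dict[str, float] = {}
    for aid, rate in entrants_per_year.items():
        if rate < 0:
            raise ValueError(f"{aid}: entrant rate must be >= 0, got {rate}")
        arch = ps.archetype(aid)
        entry = arch.entry_phase_default
        occ = [0.0] * N_PHASES
        cost = 0.0
        for k in range(entry, N_PHASES):
            inflow = rate * cumulative_pos(ps, aid, entry, k - 1)
            occ[k] = inflow * arch.phases[k].duration
            cost += inflow * arch.phases[k].cost_point
        occupancy[aid] = tuple(occ)  # type: ignore[assignment]
        cost_by_arch[aid] = cost
    return SteadyState(
        occupancy=occupancy,
        annual_cost=sum(cost_by_arch.values()),
        annual_cost_by_archetype=cost_by_arch,
    )


def annual_budget(timeline: PortfolioTimeline, year: int, ps: ParameterSet | None = None) -> float:
    """Expected cost allocated to one calendar year, $M.

    If a parameter set is given, the year must lie within its horizon.
    """
    if ps is not None and not (ps.horizon_start <= year <= ps.horizon_end):
        raise ValueError(
            f"year {year} outside horizon [{ps.horizon_start}, {ps.horizon_end}]"
        )
    return timeline.yearly_cost.get(year, 0.0)
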