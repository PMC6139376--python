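"""Deterministic expected-value progression of projects through the pipeline.

A project enters the pipeline at a chosen phase and calendar time with a
multiplicity (number of identical candidates) and a capacity factor.  The
engine propagates the *expected* candidate mass through the phases: the mass
entering phase k is the starting mass times the product of the success
probabilities of all earlier traversed phases.  Every candidate that enters a
phase incurs the full point-estimate phase cost (failures are resolved at
phase end), so the expected cost of phase k is entry mass times phase cost.

Time is continuous (decimal calendar years).  Phase intervals abut — phase
k+1 starts the instant phase k ends — and each phase's expected cost is
spread uniformly over its interval and apportioned to calendar-year buckets
[Y, Y+1) by overlap.  Expected launches are a floating-point mass credited to
the calendar year containing the launch instant; they are rounded only for
presentation, never in computation.
"""

from __future__ import annotations

import csv
import io
import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .params import N_PHASES, ParameterSet, cumulative_pos

__all__ = [
    "Project",
    "ProjectTimeline",
    "PortfolioTimeline",
    "project_timeline",
    "expected_phase_cost",
    "expected_total_cost",
    "expected_cost_per_launch",
    "aggregate",
    "round_launches_for_report",
    "read_portfolio_csv",
    "write_portfolio_csv",
    "read_portfolio_json",
]

ALL_PHASES = frozenset(range(N_PHASES))


@dataclass(frozen=True)
class Project:
    """One portfolio row: identical candidates of one archetype.

    Parameters
    ----------
    archetype
        Archetype id from the parameter registry.
    entry_phase
        Phase ordinal at which modelling begins; must be applicable for the
        archetype (a simple repurposed drug cannot enter before phase 2).
    entry_time
        Decimal calendar year of entry, e.g. ``2017.0``.
    multiplicity
        Expected number of identical candidates started (fractional allowed;
        expected-value semantics).
    capacity_factor
        Fraction in [0, 1] of the project the R&D system can absorb;
        1.0 means full capacity.
    funded_phases
        Phase ordinals whose costs the fund bears (default: all four).
    label
        Optional tag used to join health-impact inputs to this project.
    """

    archetype: str
    entry_phase: int = 0
    entry_time: float = 2017.0
    multiplicity: float = 1.0
    capacity_factor: float = 1.0
    funded_phases: frozenset[int] = ALL_PHASES
    label: str | None = None

    def __post_init__(self) -> None:
        if self.multiplicity < 0:
            raise ValueError(f"multiplicity must be >= 0, got {self.multiplicity}")
        if not (0.0 <= self.capacity_factor <= 1.0):
            raise ValueError(f"capacity_factor must be in [0, 1], got {self.capacity_factor}")
        if not (0 <= self.entry_phase < N_PHASES):
            raise ValueError(f"entry_phase must be in 0..3, got {self.entry_phase}")
        object.__setattr__(self, "funded_phases", frozenset(self.funded_phases))


@dataclass(frozen=True)
class ProjectTimeline:
    """Expected trajectory of one project through the pipeline."""

    project: Project
    phase_intervals: tuple[tuple[float, float], ...]  # [start, end) per traversed phase, by ordinal
    entry_mass: tuple[float, ...]  # expected candidates entering each traversed phase
    phase_cost: tuple[float, ...]  # expected funded cost of each traversed phase, $M
    yearly_cost: dict[int, float]  # calendar year -> expected $M
    launch_time: float  # decimal year development completes
    launch_mass: float  # expected number of launches

    @property
    def phases(self) -> range:
        """Ordinals traversed (entry phase through phase 3)."""
        return range(self.project.entry_phase, N_PHASES)

    @property
    def total_cost(self) -> float:
        return sum(self.phase_cost)


@dataclass
class PortfolioTimeline:
    """Calendar-year view of an aggregated portfolio.

    ``yearly_occupancy[year][phase]`` is the time-averaged expected number of
    candidates active in that phase during the year.
    """

    yearly_cost: dict[int, float] = field(default_factory=dict)
    yearly_occupancy: dict[int, list[float]] = field(default_factory=dict)
    yearly_launches: dict[int, float] = field(default_factory=dict)

    @property
    def years(self) -> list[int]:
        keys = set(self.yearly_cost) | set(self.yearly_occupancy) | set(self.yearly_launches)
        return sorted(keys)

    @property
    def cumulative_launches(self) -> dict[int, float]:
        total, out = 0.0, {}
        for y in self.years:
            total += self.yearly_launches.get(y, 0.0)
            out[y] = total
        return out

    def cumulative_launches_by(self, year: int) -> float:
        """Expected launches credited to calendar years up to and including ``year``."""
        return sum(v for y, v in self.yearly_launches.items() if y <= year)

    @property
    def total_cost(self) -> float:
        return sum(self.yearly_cost.values())

    def to_frame(self) -> pd.DataFrame:
        """Tidy long-format view: columns year, metric, phase, value."""
        rows: list[tuple[int, str, object, float]] = []
        cum = self.cumulative_launches
        for y in self.years:
            rows.append((y, "cost", "", self.yearly_cost.get(y, 0.0)))
            occ = self.yearly_occupancy.get(y, [0.0] * N_PHASES)
            for k in range(N_PHASES):
                rows.append((y, "occupancy", k, occ[k]))
            rows.append((y, "launches", "", self.yearly_launches.get(y, 0.0)))
            rows.append((y, "cumulative_launches", "", cum[y]))
        return pd.DataFrame(rows, columns=["year", "metric", "phase", "value"])

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Calendar bucketing helpers
# ---------------------------------------------------------------------------

def _spread_over_years(start: float, end: float, amount: float) -> dict[int, float]:
    """Apportion ``amount`` uniformly over [start, end) into year buckets.

    A zero-length interval allocates the whole amount at the instant
    ``start`` (to the year containing it).
    """
    out: dict[int, float] = {}
    if amount == 0.0:
        return out
    if end <= start:
        out[math.floor(start)] = amount
        return out
    rate = amount / (end - start)
    y = math.floor(start)
    while y < end:
        lo, hi = max(start, y), min(end, y + 1.0)
        if hi > lo:
            out[y] = out.get(y, 0.0) + rate * (hi - lo)
        y += 1
    return out


def _overlap(lo1: float, hi1: float, lo2: float, hi2: float) -> float:
    return max(0.0, min(hi1, hi2) - max(lo1, lo2))


# ---------------------------------------------------------------------------
# Core operations
# ---------------------------------------------------------------------------

def _check_entry_phase(project: Project, ps: ParameterSet) -> None:
    arch = ps.archetype(project.archetype)
    first = arch.entry_phase_default
    if project.entry_phase < first:
        raise ValueError(
            f"{project.archetype}: entry phase {project.entry_phase} precedes the "
            f"earliest applicable phase ({first})"
        )


def project_timeline(project: Project, ps: ParameterSet) -> ProjectTimeline:
    """Compute the expected trajectory of a single project.

    Phase k's interval starts at the entry time plus the durations of all
    earlier traversed phases; the mass entering it is the starting mass
    (multiplicity x capacity factor) times the cumulative probability of
    success over those phases.  Funded phase costs are entry mass times the
    point-estimate cost, spread uniformly over the phase interval.
    """
    _check_entry_phase(project, ps)
    arch = ps.archetype(project.archetype)
    if not (ps.horizon_start <= project.entry_time <= ps.horizon_end):
        warnings.warn(
            f"project entry time {project.entry_time} lies outside the modelling "
            f"horizon [{ps.horizon_start}, {ps.horizon_end}]",
            stacklevel=2,
        )
    start_mass = project.multiplicity * project.capacity_factor
    t = project.entry_time
    mass = start_mass
    intervals: list[tuple[float, float]] = []
    masses: list[float] = []
    costs: list[float] = []
    yearly: dict[int, float] = {}
    for k in range(project.entry_phase, N_PHASES):
        ph = arch.phases[k]
        start, end = t, t + ph.duration
        intervals.append((start, end))
        masses.append(mass)
        cost = mass * ph.cost_point if k in project.funded_phases else 0.0
        costs.append(cost)
        for y, v in _spread_over_years(start, end, cost).items():
            yearly[y] = yearly.get(y, 0.0) + v
        mass *= ph.pos
        t = end
    return ProjectTimeline(
        project=project,
        phase_intervals=tuple(intervals),
        entry_mass=tuple(masses),
        phase_cost=tuple(costs),
        yearly_cost=yearly,
        launch_time=t,
        launch_mass=mass,
    )


def expected_phase_cost(project: Project, phase: int, ps: ParameterSet,
                        estimate: str = "point") -> float:
    """Expected cost of one phase: entry mass times the phase cost estimate.

    Non-applicable phases cost 0.  Phases before the project's entry phase
    cost 0 (never traversed).  Unfunded phases still cost 0 to the fund.
    """
    if not (0 <= phase < N_PHASES):
        raise ValueError(f"phase must be in 0..3, got {phase}")
    if phase < project.entry_phase or phase not in project.funded_phases:
        return 0.0
    arch = ps.archetype(project.archetype)
    mass = (project.multiplicity * project.capacity_factor
            * cumulative_pos(ps, project.archetype, project.entry_phase, phase - 1))
    return mass * arch.phases[phase].cost(estimate)


def expected_total_cost(project: Project, ps: ParameterSet, estimate: str = "point") -> float:
    """Expected funded cost of a project summed over all phases, $M."""
    return sum(expected_phase_cost(project, k, ps, estimate) for k in range(N_PHASES))


def expected_cost_per_launch(archetype: str, entry_phase: int | None, ps: ParameterSet,
                             estimate: str = "point") -> float:
    """Attrition-adjusted expected R&D cost per launch, in $M.

    The expected development cost of one candidate entering at
    ``entry_phase`` (default: the archetype's earliest applicable phase),
    divided by its overall probability of reaching launch.
    """
    arch = ps.archetype(archetype)
    if entry_phase is None:
        entry_phase = arch.entry_phase_default
    proj = Project(archetype=archetype, entry_phase=entry_phase)
    _check_entry_phase(proj, ps)
    total = sum(expected_phase_cost(proj, k, ps, estimate) for k in range(N_PHASES))
    overall = cumulative_pos(ps, archetype, entry_phase, N_PHASES - 1)
    return total / overall


def aggregate(portfolio: Sequence[Project], ps: ParameterSet,
              include_horizon: bool = True) -> PortfolioTimeline:
    """Sum project timelines into a calendar-year portfolio view.

    Occupancy for year Y and phase k is the time-averaged expected number of
    candidates in the phase during [Y, Y+1): entry mass times the overlap of
    the phase interval with the year.  Launch mass is credited to the year
    containing each project's launch instant.  An empty portfolio yields a
    zero timeline over the parameter set's horizon.
    """
    tl = PortfolioTimeline()
    years: set[int] = set(ps.horizon_years) if include_horizon else set()
    ptls = [project_timeline(p, ps) for p in portfolio]
    for ptl in ptls:
        years.update(ptl.yearly_cost)
        for (start, end) in ptl.phase_intervals:
            if end > start:
                years.update(range(math.floor(start), math.ceil(end)))
        years.add(math.floor(ptl.launch_time))
    for y in sorted(years):
        tl.yearly_cost[y] = 0.0
        tl.yearly_occupancy[y] = [0.0] * N_PHASES
        tl.yearly_launches[y] = 0.0
    for ptl in ptls:
        for y, v in ptl.yearly_cost.items():
            tl.yearly_cost[y] += v
        for k, (start, end) in zip(ptl.phases, ptl.phase_intervals):
            mass = ptl.entry_mass[k - ptl.project.entry_phase]
            if end <= start or mass == 0.0:
                continue
            for y in range(math.floor(start), math.ceil(end)):
                tl.yearly_occupancy[y][k] += mass * _overlap(start, end, y, y + 1.0)
        tl.yearly_launches[math.floor(ptl.launch_time)] += ptl.launch_mass
    return tl


def round_launches_for_report(x: float) -> int:
    """Round an expected launch count to the nearest integer, half away from zero.

    For presentation only; the model itself always carries the floating-point
    expectation.
    """
    if x < 0:
        raise ValueError(f"expected launches must be >= 0, got {x}")
    return math.floor(x + 0.5)


# ---------------------------------------------------------------------------
# Portfolio I/O
# ---------------------------------------------------------------------------

_PORTFOLIO_FIELDS = ("archetype_id", "entry_phase", "entry_year", "multiplicity",
                     "capacity_factor", "funded_phases", "label")

MAX_RECOMMENDED_PROJECTS = 150


def _check_size(projects: list[Project]) -> None:
    if len(projects) > MAX_RECOMMENDED_PROJECTS:
        warnings.warn(
            f"portfolio has {len(projects)} rows; the model is designed for "
            f"up to {MAX_RECOMMENDED_PROJECTS} product development projects",
            stacklevel=3,
        )


def _project_from_record(rec: Mapping[str, object]) -> Project:
    funded = rec.get("funded_phases", "")
    if isinstance(funded, str):
        funded_set = frozenset(int(s) for s in funded.split(";") if s.strip()) if funded.strip() else ALL_PHASES
    elif funded is None:
        funded_set = ALL_PHASES
    else:
        funded_set = frozenset(int(v) for v in funded)  # type: ignore[arg-type]
    label = rec.get("label") or None
    return Project(
        archetype=str(rec["archetype_id"]),
        entry_phase=int(rec["entry_phase"]),
        entry_time=float(rec["entry_year"]),
        multiplicity=float(rec.get("multiplicity", 1.0) or 1.0),
        capacity_factor=float(rec.get("capacity_factor", 1.0) or 1.0),
        funded_phases=funded_set,
        label=str(label) if label is not None else None,
    )


def read_portfolio_csv(path: str | Path) -> list[Project]:
    """Read a portfolio definition CSV.

    Columns: archetype_id, entry_phase, entry_year, multiplicity,
    capacity_factor, funded_phases (semicolon-separated ordinals; empty means
    all), label (optional).
    """
    with open(path, newline="") as fh:
        projects = [_project_from_record(row) for row in csv.DictReader(fh)]
    _check_size(projects)
    return projects


def read_portfolio_json(path: str | Path) -> list[Project]:
    """Read a portfolio from a JSON list of row objects (same keys as the CSV)."""
    records = json.loads(Path(path).read_text())
    projects = [_project_from_record(rec) for rec in records]
    _check_size(projects)
    return projects


def write_portfolio_csv(projects: Iterable[Project], path: str | Path | None = None) -> str:
    """Write projects to the standard portfolio CSV; returns the CSV text."""
    buf = io.StringIO()
    w = csv.writer(buf, lineterminator="\n")
    w.writerow(_PORTFOLIO_FIELDS)
    for p in projects:
        funded = ";".join(str(k) for k in sorted(p.funded_phases))
        w.writerow([p.archetype, p.entry_phase, repr(p.entry_time), repr(p.multiplicity),
                    repr(p.capacity_factor), funded, p.label or ""])
    text = buf.getvalue()
    if path is not None:
        Path(path).write_text(text)
    return text
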