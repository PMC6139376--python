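"""Monte Carlo and exhaustive-enumeration cross-checks for the engine.

The portfolio model itself is deterministic: it propagates expectations.
This module provides the minimal stochastic model consistent with those
expectations — each candidate independently survives each phase with the
phase's probability of success, incurring the point-estimate cost of every
phase it enters — so the deterministic results can be validated against
simulated means and against exact enumeration of the (at most) 2^4
survive/fail paths of a single candidate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .engine import Project, project_timeline
from .params import N_PHASES, ParameterSet

__all__ = ["SimResult", "PathOutcome", "simulate", "enumerate_small",
           "expected_from_enumeration"]


@dataclass(frozen=True)
class SimResult:
    """Replicate-level simulation output with summary statistics."""

    launches: np.ndarray  # per-replicate launches (scaled by capacity factors)
    total_cost: np.ndarray  # per-replicate total cost, $M
    seed: int

    @property
    def n_reps(self) -> int:
        return self.launches.shape[0]

    @property
    def mean_launches(self) -> float:
        return float(self.launches.mean())

    @property
    def mean_cost(self) -> float:
        return float(self.total_cost.mean())

    @property
    def se_launches(self) -> float:
        return float(self.launches.std(ddof=1) / np.sqrt(self.n_reps))

    @property
    def se_cost(self) -> float:
        return float(self.total_cost.std(ddof=1) / np.sqrt(self.n_reps))


@dataclass(frozen=True)
class PathOutcome:
    """One survive/fail path of a single candidate."""

    survived: tuple[bool, ...]  # per traversed phase
    probability: float
    cost: float  # $M spent on phases entered
    launched: bool


def simulate(portfolio: Sequence[Project], ps: ParameterSet,
             n_reps: int, seed: int) -> SimResult:
    """Simulate independent Bernoulli attrition for every candidate.

    Each of a project's ``multiplicity`` candidates (which must be integral)
    survives phase k with probability pos(k) and incurs cost_point(k) for
    every phase entered.  Capacity factors scale each candidate's
    contribution to launches and costs, so simulated means estimate the
    deterministic engine's expectations.
    """
    if n_reps < 1:
        raise ValueError(f"n_reps must be >= 1, got {n_reps}")
    rng = np.random.default_rng(seed)
    launches = np.zeros(n_reps)
    total_cost = np.zeros(n_reps)
    for project in portfolio:
        m = project.multiplicity
        if m != int(m):
            raise ValueError(
                f"simulation requires integral multiplicities, got {m} "
                f"for archetype {project.archetype}"
            )
        arch = ps.archetype(project.archetype)
        cf = project.capacity_factor
        alive = np.full(n_reps, int(m), dtype=np.int64)
        for k in range(project.entry_phase, N_PHASES):
            ph = arch.phases[k]
            cost_k = ph.cost_point if k in project.funded_phases else 0.0
            total_cost += cf * cost_k * alive
            if ph.pos < 1.0:
                alive = rng.binomial(alive, ph.pos)
        launches += cf * alive
    return SimResult(launches=launches, total_cost=total_cost, seed=seed)


def enumerate_small(archetype: str, ps: ParameterSet,
                    entry_phase: int | None = None) -> list[PathOutcome]:
    """Exact outcome distribution for a single candidate.

    Enumerates every survive/fail path through the traversed phases (a
    failure ends the path; surviving all phases is a launch) with its exact
    probability and cost.  Serves as ground truth for both the deterministic
    engine and the Monte Carlo simulator.
    """
    arch = ps.archetype(archetype)
    entry = arch.entry_phase_default if entry_phase is None else entry_phase
    outcomes: list[PathOutcome] = []

    def walk(k: int, prob: float, cost: float, path: tuple[bool, ...]) -> None:
        if k == N_PHASES:
            outcomes.append(PathOutcome(path, prob, cost, launched=True))
            return
        ph = arch.phases[k]
        cost = cost + ph.cost_point
        if ph.pos < 1.0:
            outcomes.append(PathOutcome(path + (False,), prob * (1.0 - ph.pos),
                                        cost, launched=False))
        walk(k + 1, prob * ph.pos, cost, path + (True,))

    walk(entry, 1.0, 0.0, ())
    return outcomes


def expected_from_enumeration(outcomes: Sequence[PathOutcome]) -> tuple[float, float]:
    """(expected launches, expected cost) from an exact path enumeration."""
    launches = sum(o.probability for o in outcomes if o.launched)
    cost = sum(o.probability * o.cost for o in outcomes)
    return launches, cost
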