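"""Deterministic generators of synthetic portfolios and parameter variants.

Real funder portfolios are proprietary; these generators produce random but
structurally valid stand-ins (entry phases respect archetype applicability,
capacity factors in range) for tests and examples, reproducibly from a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .engine import ALL_PHASES, Project
from .params import (ARCHETYPE_IDS, N_PHASES, ParameterSet, PhaseParams,
                     load_default_params, validate_params)

__all__ = ["FixtureSpec", "random_portfolio", "perturb_params"]


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for a synthetic portfolio."""

    n_projects: int
    archetype_pool: tuple[str, ...] = ARCHETYPE_IDS
    year_range: tuple[int, int] = (2017, 2025)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_projects < 0:
            raise ValueError(f"n_projects must be >= 0, got {self.n_projects}")
        if self.n_projects > 0 and not self.archetype_pool:
            raise ValueError("archetype pool may not be empty when n_projects > 0")
        if self.year_range[1] < self.year_range[0]:
            raise ValueError(f"invalid year range {self.year_range}")


def random_portfolio(spec: FixtureSpec, ps: ParameterSet | None = None) -> list[Project]:
    """Generate a reproducible portfolio of valid projects.

    Each project enters at its archetype's earliest applicable phase (so the
    portfolio is always valid against the registry); entry years are drawn
    uniformly from the spec's range, multiplicities from 1..5, capacity
    factors from {1.0} u [0.5, 1.0).
    """
    ps = ps if ps is not None else load_default_params()
    rng = np.random.default_rng(spec.seed)
    projects: list[Project] = []
    for _ in range(spec.n_projects):
        aid = spec.archetype_pool[rng.integers(len(spec.archetype_pool))]
        arch = ps.archetype(aid)
        entry = arch.entry_phase_default
        year = float(rng.integers(spec.year_range[0], spec.year_range[1] + 1))
        mult = int(rng.integers(1, 6))
        cf = 1.0 if rng.random() < 0.5 else float(np.round(rng.uniform(0.5, 1.0), 2))
        projects.append(Project(archetype=aid, entry_phase=entry, entry_time=year,
                                multiplicity=mult, capacity_factor=cf,
                                funded_phases=ALL_PHASES))
    return projects


def perturb_params(ps: ParameterSet, scale: float, seed: int) -> ParameterSet:
    """Multiplicatively jitter costs and durations, and jitter-and-clamp PoS.

    ``scale`` in [0, 0.5] bounds the relative perturbation.  Pass-through
    phases are untouched; cost bounds are scaled by a common factor per
    phase so ordering invariants survive; probabilities are clamped to
    (0, 1].  The result always validates.
    """
    if not (0.0 <= scale <= 0.5):
        raise ValueError(f"scale must be in [0, 0.5], got {scale}")
    if scale == 0.0:
        return ps
    rng = np.random.default_rng(seed)
    new_arches = {}
    for aid, arch in ps.archetypes.items():
        phases = []
        for ph in arch.phases:
            if not ph.applicable:
                phases.append(ph)
                continue
            cost_f = 1.0 + rng.uniform(-scale, scale)
            dur_f = 1.0 + rng.uniform(-scale, scale)
            pos = ph.pos * (1.0 + rng.uniform(-scale, scale))
            pos = min(1.0, max(1e-6, pos))
            phases.append(PhaseParams(
                cost_low=ph.cost_low * cost_f,
                cost_high=ph.cost_high * cost_f,
                cost_point=ph.cost_point * cost_f,
                pos=pos,
                duration=ph.duration * dur_f,
                applicable=True,
            ))
        new_arches[aid] = replace(arch, phases=tuple(phases))
    out = replace(ps, archetypes=new_arches)
    violations = validate_params(out)
    if violations:  # defensive: clamping should guarantee validity
        raise AssertionError("perturbed parameters failed validation: " + "; ".join(violations))
    return out
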