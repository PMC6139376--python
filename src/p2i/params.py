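"""Archetype parameter registry: phase costs, probabilities of success, cycle times.

The model describes product development as four ordered phases — preclinical,
phase 1, phase 2, phase 3 — for eleven intervention archetypes spanning five
product categories (vaccine, new chemical entity, repurposed drug, biologic,
diagnostic).  Each archetype carries, per phase, a development-cost estimate
(lower bound, upper bound, point estimate, in millions of USD), a probability
of success (the chance a candidate entering the phase completes it and
advances), and a cycle time in years.

Diagnostics develop through three named stages ("selection and validation of
markers", "development", "regulated trials beyond EUO/CE") which occupy the
first three slots of the same four-slot structure; the remaining slot is a
pass-through.  Phases that do not apply to an archetype (e.g. preclinical for
a simple repurposed drug, which enters directly at phase 2) are modelled as
pass-throughs: zero cost, zero duration, probability of success 1.

All probabilities are stored as fractions, all money in $M, all durations in
years.  The registry is data-driven and can be exported to / imported from
CSV so any parameter can be overridden.
"""

from __future__ import annotations

import csv
import io
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

__all__ = [
    "PHASE_LABELS",
    "DIAGNOSTIC_PHASE_LABELS",
    "ARCHETYPE_IDS",
    "PhaseParams",
    "ArchetypeParams",
    "ParameterSet",
    "ParameterIntegrityError",
    "load_default_params",
    "validate_params",
    "cumulative_pos",
    "export_params_csv",
    "import_params_csv",
]

#: Canonical labels for the four phase slots (ordinals 0..3).
PHASE_LABELS = ("preclinical", "phase 1", "phase 2", "phase 3")

#: Diagnostics map their three named stages onto ordinals 0..2.
DIAGNOSTIC_PHASE_LABELS = (
    "Selection and validation of markers",
    "Development",
    "Regulated trials beyond EUO/CE",
    "(pass-through)",
)

N_PHASES = 4


class ParameterIntegrityError(ValueError):
    """Raised when a parameter set fails its structural invariants."""


@dataclass(frozen=True)
class PhaseParams:
    """Cost, success probability and duration for one phase of one archetype.

    ``applicable=False`` marks a pass-through slot: the candidate traverses it
    instantly, at no cost and with certainty.
    """

    cost_low: float = 0.0  # $M
    cost_high: float = 0.0  # $M
    cost_point: float = 0.0  # $M
    pos: float = 1.0  # probability of success, fraction in (0, 1]
    duration: float = 0.0  # years
    applicable: bool = True

    def cost(self, estimate: str = "point") -> float:
        """Return the cost under the named estimate ('low', 'point', 'high')."""
        try:
            return {"low": self.cost_low, "point": self.cost_point, "high": self.cost_high}[estimate]
        except KeyError:
            raise ValueError(f"unknown cost estimate {estimate!r}; use 'low', 'point' or 'high'")


#: A non-applicable slot: zero cost/duration, certain pass-through.
PASS_THROUGH = PhaseParams(0.0, 0.0, 0.0, 1.0, 0.0, applicable=False)


@dataclass(frozen=True)
class ArchetypeParams:
    """One of the eleven product archetypes with its four ordered phase slots."""

    id: str
    category: str  # vaccine | NCE | repurposed drug | biologic | diagnostic
    subtype: str
    phases: tuple[PhaseParams, PhaseParams, PhaseParams, PhaseParams]
    display_name: str = ""

    @property
    def entry_phase_default(self) -> int:
        """Earliest applicable phase ordinal (phase 2 for simple repurposed drugs)."""
        for k, ph in enumerate(self.phases):
            if ph.applicable:
                return k
        return 0

    @property
    def total_cycle_time(self) -> float:
        """Sum of the four phase durations in years."""
        return sum(ph.duration for ph in self.phases)

    def phase_labels(self) -> tuple[str, ...]:
        return DIAGNOSTIC_PHASE_LABELS if self.category == "diagnostic" else PHASE_LABELS


@dataclass(frozen=True)
class ParameterSet:
    """A full model parameterization: archetype registry plus global settings.

    Parameters
    ----------
    archetypes
        Mapping of archetype id to :class:`ArchetypeParams`.
    daly_value
        Economic valuation of one DALY averted, in USD (default 500).
    horizon_start, horizon_end
        Calendar-year modelling window (defaults 2017–2030, extensible
        to 2040).
    """

    archetypes: Mapping[str, ArchetypeParams]
    daly_value: float = 500.0
    horizon_start: int = 2017
    horizon_end: int = 2030

    def archetype(self, archetype_id: str) -> ArchetypeParams:
        try:
            return self.archetypes[archetype_id]
        except KeyError:
            known = ", ".join(sorted(self.archetypes))
            raise KeyError(f"unknown archetype {archetype_id!r}; known: {known}")

    @property
    def horizon_years(self) -> range:
        return range(self.horizon_start, self.horizon_end + 1)


# ---------------------------------------------------------------------------
# Default registry
#
# Columns per phase: (cost_low, cost_high, cost_point, pos, duration).
# None marks a non-applicable slot (pass-through).  Probabilities are
# fractions of the printed percentages; costs in $M; durations in years.
# ---------------------------------------------------------------------------

_R = tuple  # row shorthand

_DEFAULT_TABLE: dict[str, tuple[str, str, str, tuple] ] = {
    "vaccine_simple": (
        "vaccine", "simple", "Simple vaccine",
        (_R((3.3, 10.0, 6.7, 0.410, 3.36)),
         _R((1.8, 2.7, 2.2, 0.684, 1.57)),
         _R((7.4, 19.0, 13.2, 0.459, 2.23)),
         _R((56.6, 165.6, 111.1, 0.708, 2.33))),
    ),
    "vaccine_complex": (
        "vaccine", "complex", "Complex vaccine",
        (_R((8.3, 24.9, 16.6, 0.410, 3.33)),
         _R((1.9, 3.0, 2.5, 0.500, 1.97)),
         _R((7.8, 20.0, 13.9, 0.216, 3.71)),
         _R((67.9, 198.7, 133.3, 0.636, 3.50))),
    ),
    "nce_simple": (
        "NCE", "simple", "Simple new chemical entity",
        (_R((2.5, 7.5, 5.0, 0.650, 2.49)),
         _R((1.8, 2.7, 2.2, 0.597, 1.80)),
         _R((3.7, 7.9, 5.8, 0.388, 3.38)),
         _R((11.5, 54.1, 32.8, 0.691, 3.18))),
    ),
    "nce_innovative": (
        "NCE", "innovative", "Innovative new chemical entity",
        (_R((5.0, 10.0, 7.5, 0.600, 2.70)),
         _R((4.4, 5.3, 4.8, 0.519, 1.81)),
         _R((3.9, 8.3, 6.1, 0.284, 3.35)),
         _R((12.1, 55.4, 34.5, 0.578, 3.10))),
    ),
    "nce_complex": (
        "NCE", "complex", "Complex new chemical entity",
        (_R((7.5, 12.5, 10.0, 0.550, 2.87)),
         _R((6.9, 7.9, 7.4, 0.572, 1.93)),
         _R((4.1, 8.7, 6.4, 0.197, 3.51)),
         _R((12.6, 59.6, 36.1, 0.403, 2.80))),
    ),
    "repurposed_simple": (
        "repurposed drug", "simple", "Simple repurposed drug",
        (None,
         None,
         _R((3.7, 7.9, 5.8, 0.457, 2.14)),
         _R((10.0, 25.2, 17.6, 0.681, 2.14))),
    ),
    "repurposed_complex": (
        "repurposed drug", "complex", "Complex repurposed drug",
        (_R((2.5, 7.5, 5.0, 0.750, 2.33)),
         _R((1.7, 2.7, 2.2, 0.585, 1.63)),
         _R((3.7, 7.9, 5.8, 0.457, 2.14)),
         _R((10.0, 25.2, 17.6, 0.681, 2.14))),
    ),
    "biologic_simple": (
        "biologic", "simple", "Simple biologic",
        (_R((5.4, 16.2, 10.8, 0.750, 3.29)),
         _R((1.9, 3.0, 2.4, 0.662, 1.62)),
         _R((4.5, 10.5, 7.5, 0.443, 2.47)),
         _R((27.7, 80.5, 54.1, 0.709, 2.10))),
    ),
    "biologic_complex": (
        "biologic", "complex", "Complex biologic",
        (_R((16.2, 27.0, 21.6, 0.770, 3.24)),
         _R((7.0, 8.3, 7.6, 0.696, 1.49)),
         _R((5.0, 11.6, 8.3, 0.322, 4.16)),
         _R((30.5, 88.5, 59.5, 0.625, 3.38))),
    ),
    "diagnostic_assay": (
        "diagnostic", "assay", "Diagnostic assay development",
        (_R((1.0, 5.0, 3.0, 0.500, 1.00)),
         _R((1.0, 3.0, 2.0, 1.000, 1.25)),
         _R((1.0, 6.0, 3.5, 1.000, 1.33)),
         None),
    ),
    "diagnostic_platform": (
        "diagnostic", "platform", "Simple technical platform development",
        (None,
         _R((50.0, 150.0, 100.0, 0.750, 2.50)),
         _R((1.0, 6.0, 3.5, 1.000, 2.00)),
         None),
    ),
}

ARCHETYPE_IDS = tuple(_DEFAULT_TABLE)


def _build_archetype(aid: str) -> ArchetypeParams:
    category, subtype, display, rows = _DEFAULT_TABLE[aid]
    phases = tuple(
        PASS_THROUGH if row is None
        else PhaseParams(cost_low=row[0], cost_high=row[1], cost_point=row[2],
                         pos=row[3], duration=row[4])
        for row in rows
    )
    return ArchetypeParams(id=aid, category=category, subtype=subtype,
                           phases=phases, display_name=display)


def load_default_params() -> ParameterSet:
    """Build the default parameter registry for all eleven archetypes.

    Returns
    -------
    ParameterSet
        Registry with every transcribed value, percentages as fractions and
        non-applicable phases marked as pass-throughs.

    Raises
    ------
    ParameterIntegrityError
        If the embedded table fails validation (should never happen).
    """
    ps = ParameterSet(archetypes={aid: _build_archetype(aid) for aid in ARCHETYPE_IDS})
    violations = validate_params(ps)
    if violations:
        raise ParameterIntegrityError(
            "default parameter table failed validation: " + "; ".join(violations)
        )
    return ps


def validate_params(ps: ParameterSet) -> list[str]:
    """Check every invariant of a parameter set; return violation descriptions.

    An empty list means the set is valid.  Each violation names the archetype,
    phase ordinal and offending field.
    """
    out: list[str] = []
    if not ps.daly_value > 0:
        out.append(f"daly_value: must be > 0, got {ps.daly_value}")
    if not ps.horizon_end > ps.horizon_start:
        out.append(f"horizon: horizon_end {ps.horizon_end} must exceed horizon_start {ps.horizon_start}")
    for aid, arch in ps.archetypes.items():
        if len(arch.phases) != N_PHASES:
            out.append(f"{aid}: expected {N_PHASES} phases, got {len(arch.phases)}")
            continue
        for k, ph in enumerate(arch.phases):
            where = f"{aid}/phase {k}"
            if not (0.0 < ph.pos <= 1.0) or math.isnan(ph.pos):
                out.append(f"{where}: pos must be in (0, 1], got {ph.pos}")
            if ph.cost_low < 0:
                out.append(f"{where}: cost_low must be >= 0, got {ph.cost_low}")
            if ph.cost_high < ph.cost_low:
                out.append(f"{where}: cost_high {ph.cost_high} < cost_low {ph.cost_low}")
            if not (ph.cost_low <= ph.cost_point <= ph.cost_high):
                out.append(f"{where}: cost_point {ph.cost_point} outside [{ph.cost_low}, {ph.cost_high}]")
            if ph.duration < 0:
                out.append(f"{where}: duration must be >= 0, got {ph.duration}")
            if not ph.applicable:
                if ph.cost_point != 0 or ph.cost_low != 0 or ph.cost_high != 0:
                    out.append(f"{where}: non-applicable phase must have zero cost")
                if ph.duration != 0:
                    out.append(f"{where}: non-applicable phase must have zero duration")
                if ph.pos != 1.0:
                    out.append(f"{where}: non-applicable phase must have pos 1.0, got {ph.pos}")
    return out


def cumulative_pos(ps: ParameterSet, archetype: str, from_phase: int, through_phase: int) -> float:
    """Product of per-phase success probabilities over an inclusive phase range.

    The chance that a candidate entering ``from_phase`` advances through
    ``through_phase``.  The empty range ``from_phase == through_phase + 1``
    returns 1.0 (empty product); a more inverted range is an error.
    """
    arch = ps.archetype(archetype)
    if not (0 <= from_phase <= N_PHASES) or not (-1 <= through_phase < N_PHASES):
        raise ValueError(f"phase ordinals out of range: {from_phase}..{through_phase}")
    if from_phase > through_phase + 1:
        raise ValueError(
            f"inverted phase range: from_phase {from_phase} > through_phase {through_phase} + 1"
        )
    p = 1.0
    for k in range(max(from_phase, 0), through_phase + 1):
        p *= arch.phases[k].pos
    return p


# ---------------------------------------------------------------------------
# CSV round trip
# ---------------------------------------------------------------------------

_CSV_FIELDS = ("archetype_id", "phase_ordinal", "cost_low", "cost_high",
               "cost_point", "pos", "duration", "applicable")


def export_params_csv(ps: ParameterSet, path: str | Path | io.TextIOBase | None = None) -> str:
    """Serialize the registry to CSV; returns the CSV text.

    Floats are written with ``repr`` so the default registry round-trips
    bit-exactly through :func:`import_params_csv`.
    """
    buf = io.StringIO()
    w = csv.writer(buf, lineterminator="\n")
    w.writerow(_CSV_FIELDS)
    for aid, arch in ps.archetypes.items():
        for k, ph in enumerate(arch.phases):
            w.writerow([aid, k, repr(ph.cost_low), repr(ph.cost_high),
                        repr(ph.cost_point), repr(ph.pos), repr(ph.duration),
                        int(ph.applicable)])
    text = buf.getvalue()
    if path is not None:
        if isinstance(path, (str, Path)):
            Path(path).write_text(text)
        else:
            path.write(text)
    return text


def import_params_csv(source: str | Path | io.TextIOBase,
                      base: ParameterSet | None = None) -> ParameterSet:
    """Read a registry CSV (as written by :func:`export_params_csv`).

    Archetype metadata (category, subtype) is taken from ``base`` (default:
    the built-in registry) when the archetype id is known, so user overrides
    of individual numbers keep their classification.
    """
    if isinstance(source, Path) or (isinstance(source, str) and "\n" not in source):
        text = Path(source).read_text()
    elif isinstance(source, str):
        text = source
    else:
        text = source.read()
    base = base if base is not None else load_default_params()
    rows = list(csv.DictReader(io.StringIO(text)))
    slots: dict[str, dict[int, PhaseParams]] = {}
    for row in rows:
        aid = row["archetype_id"]
        k = int(row["phase_ordinal"])
        slots.setdefault(aid, {})[k] = PhaseParams(
            cost_low=float(row["cost_low"]),
            cost_high=float(row["cost_high"]),
            cost_point=float(row["cost_point"]),
            pos=float(row["pos"]),
            duration=float(row["duration"]),
            applicable=bool(int(row["applicable"])),
        )
    archetypes: dict[str, ArchetypeParams] = {}
    for aid, by_ord in slots.items():
        if sorted(by_ord) != list(range(N_PHASES)):
            raise ParameterIntegrityError(f"{aid}: CSV must define phase ordinals 0..3")
        phases = tuple(by_ord[k] for k in range(N_PHASES))
        if aid in base.archetypes:
            archetypes[aid] = replace(base.archetypes[aid], phases=phases)
        else:
            archetypes[aid] = ArchetypeParams(id=aid, category="custom", subtype="custom",
                                              phases=phases, display_name=aid)
    ps = ParameterSet(archetypes=archetypes, daly_value=base.daly_value,
                      horizon_start=base.horizon_start, horizon_end=base.horizon_end)
    violations = validate_params(ps)
    if violations:
        raise ParameterIntegrityError("imported parameters invalid: " + "; ".join(violations))
    return ps
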