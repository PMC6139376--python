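"""Health impact of launched products: DALYs averted, deaths averted, value.

The impact of a single launched intervention is a direct multiplication: the
annual disease burden (DALYs, deaths — 2012 low- and middle-income-country
estimates supplied by the user) times the user's informed estimate of the
fractional reduction the product would achieve.  DALYs averted are valued at
a conservative $500 per DALY by default.  There is deliberately no adoption
curve, coverage ramp or discounting; the figure informs priority setting,
not a precise economic forecast.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

from .engine import Project, project_timeline
from .params import ParameterSet

__all__ = [
    "ImpactInput",
    "ImpactEstimate",
    "YearImpact",
    "estimate_impact",
    "portfolio_impact",
    "read_impact_config",
]


@dataclass(frozen=True)
class ImpactInput:
    """Disease burden and expected fractional reductions for one target disease."""

    disease: str
    burden_dalys: float = 0.0  # DALYs/year
    burden_deaths: float = 0.0  # deaths/year
    reduction_dalys: float = 0.0  # fraction in [0, 1]
    reduction_deaths: float = 0.0  # fraction in [0, 1]

    def __post_init__(self) -> None:
        if self.burden_dalys < 0 or self.burden_deaths < 0:
            raise ValueError("disease burdens must be >= 0")
        for name in ("reduction_dalys", "reduction_deaths"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")


@dataclass(frozen=True)
class ImpactEstimate:
    """Annual impact of a single launched intervention."""

    dalys_averted: float
    deaths_averted: float
    economic_value: float  # USD/year

    def scaled(self, factor: float) -> "ImpactEstimate":
        return ImpactEstimate(self.dalys_averted * factor,
                              self.deaths_averted * factor,
                              self.economic_value * factor)

    def __add__(self, other: "ImpactEstimate") -> "ImpactEstimate":
        return ImpactEstimate(self.dalys_averted + other.dalys_averted,
                              self.deaths_averted + other.deaths_averted,
                              self.economic_value + other.economic_value)


ZERO_IMPACT = ImpactEstimate(0.0, 0.0, 0.0)


@dataclass(frozen=True)
class YearImpact:
    """Impact credited to one calendar year, in two views.

    ``expected`` weights each project's per-launch impact by its fractional
    expected launch mass; ``per_whole_launch`` counts each launching project
    as one whole launched intervention.
    """

    year: int
    expected: ImpactEstimate
    per_whole_launch: ImpactEstimate


def estimate_impact(inp: ImpactInput, ps: ParameterSet) -> ImpactEstimate:
    """Impact of one launched intervention: burden times expected reduction.

    Economic value is DALYs averted times the parameter set's per-DALY
    valuation (default $500).
    """
    dalys = inp.burden_dalys * inp.reduction_dalys
    deaths = inp.burden_deaths * inp.reduction_deaths
    return ImpactEstimate(dalys_averted=dalys, deaths_averted=deaths,
                          economic_value=dalys * ps.daly_value)


def portfolio_impact(portfolio: Sequence[Project],
                     impacts: Mapping[str, ImpactInput],
                     ps: ParameterSet) -> list[YearImpact]:
    """Per-year expected impact of a portfolio's launches.

    Each project is joined to an :class:`ImpactInput` by its ``label``;
    projects without a matching label contribute no impact.  A project's
    launch is credited to the calendar year containing its launch instant,
    weighted by its expected launch mass (``expected`` view) or counted as a
    single whole launch (``per_whole_launch`` view).
    """
    by_year: dict[int, tuple[ImpactEstimate, ImpactEstimate]] = {}
    for project in portfolio:
        if project.label is None or project.label not in impacts:
            continue
        per_launch = estimate_impact(impacts[project.label], ps)
        ptl = project_timeline(project, ps)
        y = int(ptl.launch_time)
        exp_prev, whole_prev = by_year.get(y, (ZERO_IMPACT, ZERO_IMPACT))
        by_year[y] = (exp_prev + per_launch.scaled(ptl.launch_mass),
                      whole_prev + per_launch)
    return [YearImpact(year=y, expected=e, per_whole_launch=w)
            for y, (e, w) in sorted(by_year.items())]


def read_impact_config(path: str | Path) -> dict[str, ImpactInput]:
    """Load impact inputs keyed by disease label from CSV or JSON.

    CSV columns / JSON keys: disease, burden_dalys, burden_deaths,
    reduction_dalys, reduction_deaths.
    """
    p = Path(path)
    if p.suffix.lower() == ".json":
        records = json.loads(p.read_text())
    else:
        with open(p, newline="") as fh:
            records = list(csv.DictReader(fh))
    out: dict[str, ImpactInput] = {}
    for rec in records:
        inp = ImpactInput(
            disease=str(rec["disease"]),
            burden_dalys=float(rec.get("burden_dalys", 0) or 0),
            burden_deaths=float(rec.get("burden_deaths", 0) or 0),
            reduction_dalys=float(rec.get("reduction_dalys", 0) or 0),
            reduction_deaths=float(rec.get("reduction_deaths", 0) or 0),
        )
        out[inp.disease] = inp
    return out
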