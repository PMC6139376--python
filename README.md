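# p2i — portfolio-to-impact modelling of health product R&D

`p2i` is a deterministic portfolio model for funders of health product
research and development, particularly for poverty-related and neglected
diseases where conventional market incentives fail. Given a portfolio of
candidate products, it estimates **annual funding needs**, the **expected
number of candidates** moving through each development phase, **expected
product launches** over a calendar horizon, and the **health impact** (DALYs
and deaths averted, and their economic value) of those launches.

## The model

Products are classified into eleven *archetypes* — simple/complex vaccines,
simple/innovative/complex new chemical entities (NCEs), simple/complex
repurposed drugs, simple/complex biologics, and two diagnostic archetypes
(assay development, technical platform development). Each archetype carries,
for each of four development phases (preclinical, phase 1, phase 2,
phase 3), three parameters:

- a development cost `c_k` (lower bound, point estimate, upper bound, $M),
- a probability of success `p_k` (the complement of attrition), and
- a cycle time `d_k` (years).

A project starting `m` candidates at entry phase `e` propagates *expected
candidate mass* through the chain: the mass entering phase `k` is

    n_k = m · γ · ∏_{j=e}^{k-1} p_j

where `γ` is a capacity factor in [0, 1]. Every candidate entering a phase
incurs the full phase cost (failures are resolved at phase end), so the
expected cost of phase `k` is `n_k · c_k`, spread uniformly over the phase's
time interval and booked to calendar years by overlap. The expected launch
count `n_3 · p_3` is a floating-point expectation, rounded only for
presentation. Phases that do not apply to an archetype (e.g. preclinical for
a simple repurposed drug, which enters at phase 2) are pass-throughs: zero
cost, zero duration, certain success.

On top of the engine sit:

- a **planner** — prospective ("fund two phase-1 projects per year") and
  retrospective ("I want one launch by 2030": entrants = target / ∏ p_k,
  entry year = target year − Σ d_k), plus steady-state portfolio sizing via
  flow equilibrium (occupancy of phase k = inflow rate × d_k);
- an **impact module** — for a launched intervention, DALYs averted =
  disease burden × expected fractional reduction, valued at $500 per DALY
  by default;
- a **scenario runner** — seven built-in fund sizes from $1M/yr
  (coordination only) to a $500M/yr global fund, with archetype-mix
  strategies ("quick wins", "innovation", "mixed") scaled to fit the budget;
- a **Monte Carlo / exact-enumeration oracle** used to validate the
  deterministic expectations in the test suite.

## Worked example

Ten simple repurposed drug candidates entering phase 2 in 2017:

```python
from p2i import *

ps = load_default_params()
proj = Project("repurposed_simple", entry_phase=2, entry_time=2017.0, multiplicity=10)
tl = aggregate([proj], ps)
print(tl.cumulative_launches_by(2030))   # 3.112
print(tl.total_cost)                     # 138.43
print(tl.yearly_cost[2017])              # 27.10
```

Each candidate survives phase 2 with probability 0.457 and phase 3 with
0.681, so 10 candidates yield 10 × 0.457 × 0.681 ≈ **3.112 expected
launches** (reported as 3) in 2021, after two 2.14-year phases. The expected
cost is 10 × (5.8 + 0.457 × 17.6) ≈ **$138.4M**, of which 10 × 5.8/2.14 ≈
**$27.1M** falls in 2017 under uniform within-phase spreading.

Retrospectively, one expected simple-vaccine launch by 2030 requires
1/0.0911 ≈ **10.97 entrants** at preclinical in 2020.51 (9.49 years of
cycle time before the target year):

```bash
$ p2i plan solve --archetype vaccine_simple --target-phase launch --count 1 --by-year 2030
entrants needed: 10.9727 (ceil: 11)
entry phase: 0, entry year: 2020.51
```

A $100M/yr fund pursuing quick wins:

```bash
$ p2i scenario run --name scenario-5 --strategy quick_wins
Scenario: scenario-5
  annual fund size: 100.0 $M
  ...
  new projects initiated per year: 7.81
  steady-state portfolio size: 26.5
  expected launches by 2030: 22.58 (rounded: 23)
```

The fund sustains about 7.8 new projects per year, a steady-state portfolio
of ~27 active projects, and ~23 expected launches by 2030 under this
(illustrative) strategy mix.

`p2i params export`, `p2i params cost-per-launch`, `p2i impact` and
`p2i simulate` expose the registry, per-archetype cost-per-launch, the
impact calculator and the validation simulator; `p2i --help` lists
everything.

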