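# Methods

## Model

`p2i` implements a deterministic expected-value model of product-development
pipelines. A portfolio row (project) is defined by an archetype, an entry
phase, an entry time (decimal calendar year), a multiplicity `m` (number of
identical candidates, fractional allowed), a capacity factor `γ ∈ [0, 1]`
and a set of funded phases. For each traversed phase `k` the expected
candidate mass entering is `n_k = m·γ·∏_{j<k} p_j` (product over traversed
phases), the expected funded cost is `n_k·c_k`, and the expected launch
count is `n_3·p_3`. Everything downstream — calendar budgets, occupancies,
launches, impact — is a linear functional of these masses, so all outputs
are exactly homogeneous of degree 1 in `m`, `γ` and entry rates. The model
carries expectations, not distributions: there is no uncertainty or risk
propagation, and point estimates drive all central results (the low/high
cost bounds give a deterministic range, not a confidence interval).

### Attrition and cost timing

Success is evaluated at phase **end**: every candidate that enters a phase
spends the full phase budget, including those that fail. This is the natural
reading of per-phase transition probabilities — a failed trial still has to
be paid for.

### Calendar bucketing

Time is continuous; phase intervals abut, so a project's phases partition
`[entry, launch)`. Each phase's expected cost is spread **uniformly** over
its interval and apportioned to half-open calendar years `[Y, Y+1)` by
overlap. The convention for lumping within a phase is genuinely open (an
alternative books the whole phase cost at phase start); both conserve
totals, only annual profiles differ, and uniform spreading gives
well-defined annual budgets. Zero-duration phases (pass-throughs) allocate
their — necessarily zero under the defaults — cost at the instant of entry.
Occupancy for year Y and phase k is the time-averaged expected number of
candidates in the phase during the year (`n_k` × interval overlap with the
year). Launch mass is credited to the calendar year containing the launch
instant.

### Parameters

The registry holds, per archetype and phase: cost lower/upper bounds and
point estimate ($M), probability of success (fraction in (0, 1]) and cycle
time (years). Probabilities are stored as fractions throughout; money stays
in $M until reporting. Non-applicable phases (preclinical and phase 1 for
simple repurposed drugs, the first slot for platform diagnostics, the last
slot for both diagnostics) are pass-throughs with cost 0, duration 0,
probability 1 — this keeps one uniform four-slot engine for all archetypes,
with the three named diagnostic stages mapped onto ordinals 0–2. Diagnostic
slots with no published cost are treated as absent stages, not zero-cost
stages. The default entry phase of an archetype is its earliest applicable
phase (phase 2 for simple repurposed drugs — they already have sufficient
safety data — and the "development" slot for platform diagnostics).

Global settings: the modelling horizon defaults to 2017–2030 and extends to
2040 or beyond by replacing `horizon_end`; DALYs averted are valued at $500
each by default, a deliberately conservative figure meant for comparing
options, not for estimating true economic value.

The registry is data-driven: it exports to and imports from a flat CSV
(archetype, phase ordinal, costs, PoS, duration, applicability), round-trips
bit-exactly, and any cell can be overridden by the user. Imports are
re-validated; violations name the archetype, phase and field.

## Planner

Prospective plans expand entry-schedule rows (archetype, entry phase, year,
entrants/year) into projects and aggregate them. Retrospective plans invert
the chain: entrants = target count / cumulative PoS from entry to the phase
preceding the target (full chain for a launch target), entry year = target
year − traversed cycle time. Fractional entrants are the primary output
(expected-value semantics, matching the engine); an integerized ceiling is
reported alongside. A target whose implied entry year precedes the horizon
start is infeasible and raises. The documented cap of 150 portfolio rows is
a soft warning, not a hard limit.

Steady-state sizing applies flow equilibrium (Little's law): with constant
entrants per year, inflow to phase k is the entry rate times the cumulative
PoS of earlier phases; occupancy is inflow × duration; annual cost is
inflow × phase cost. The acceptance suite verifies this against the long-run
occupancy of an explicit constant-entrant plan over ≥ 3 cycle times.

## Impact

Impact of one launched intervention = user-supplied annual disease burden
(DALYs, deaths; 2012 low- and middle-income-country estimates are the
intended source) × user-supplied expected fractional reduction; economic
value = DALYs averted × $/DALY. There is intentionally no adoption curve,
coverage ramp or discounting — the calculation is a single multiplication
and is documented as such. Burden tables are not bundled; they are user
inputs. Portfolio-level impact is reported in two views: expectation-
weighted (per-launch impact × fractional expected launch mass credited to
each year) and per-whole-launch (each launching project counted once),
since launches are binary in reality but fractional in expectation.

## Scenarios

Seven built-in fund scenarios span $1M/yr to $500M/yr; the two smallest
fund coordination/prioritization only and start no projects. Operational
scenarios choose a strategy template — archetype-mix entrant weights. The
shipped templates (quick wins: 70% simple repurposed, 20% complex
repurposed, 10% assay diagnostics; innovation: complex vaccines/NCEs/
biologics, innovative NCEs, platform diagnostics; mixed: 50/50 blend) are
**illustrative** and overridable in config: the strategy names are
established, their exact compositions are not, so scenario outputs reproduce
structure rather than any specific published figures. Budget fitting scales
the mix by the largest factor whose *steady-state* annual cost fits the
fund size (cost is linear in entrants, so the factor is a single division);
ramp-up years underspend, which the budget trace reports — the fund size is
treated as an annual disbursement capacity, fully available for projects in
operational scenarios (coordination overhead within them is not modelled
separately). Reports are plain text and tidy CSV (year, metric, phase,
value); all runs are fully deterministic.

## Validation oracle

Because the model is deterministic, the package ships an independent
stochastic oracle for testing: each candidate survives each phase as an
independent Bernoulli trial with the phase PoS, paying the point-estimate
cost of each phase entered — the minimal stochastic model whose
expectations coincide with the engine. Two routes check the engine: exact
enumeration of the ≤ 2⁴ survive/fail paths of a single candidate (equality
to 1e-12 relative for every archetype) and a seeded Monte Carlo simulator
(means within 3 standard errors at 10⁵ replicates). Capacity factors scale
each candidate's simulated contribution so means stay comparable;
multiplicities must be integral for simulation.

## Synthetic fixtures

Real funder portfolios are proprietary, so tests use generated stand-ins:
seeded random portfolios (archetypes drawn from a pool, entry at the
archetype's earliest applicable phase, entry years 2017–2025,
multiplicities 1–5, capacity factors in {1} ∪ [0.5, 1)) and seeded
multiplicative parameter jitter (common factor per phase across the three
cost fields so bound ordering survives; PoS clamped to (0, 1]; jitter
bounded at ±50%). These fixtures exercise structural validity, conservation
and linearity; they do not emulate disease-specific pipeline composition,
correlated project outcomes, or duration/cost variability, so passing tests
demonstrate internal consistency of the expected-value machinery, not
predictive accuracy for any real pipeline.

## Numerical choices and limitations

- Conservation (calendar allocations vs. direct expected costs) holds to
  1e-9 relative; oracle/engine equality to 1e-12 relative; steady state vs.
  long-run plan to 1e-6 relative. All comfortably met since every quantity
  is a short product/sum of doubles.
- Launch counts are rounded half-away-from-zero, and only in reports.
- Problem sizes are tiny by construction (11 archetypes × 4 phases;
  portfolios of tens of rows; Monte Carlo at 10⁵ replicates), chosen as
  ample for 3-standard-error discrimination of the binomial means involved.
- Not modelled, by design: market dimensions (price, demand, volumes,
  profits), cost discounting, stochastic timing or cost variation,
  portfolio optimization under a budget, discovery/lead-optimization and
  post-phase-III costs, and capacity constraints beyond the per-row
  multiplicative factor (whether capacity should instead gate new starts
  per year is an open interpretation; the per-row multiplicative reading is
  implemented).
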