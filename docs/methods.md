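# Methods

## The model

`carejourney` implements an operational model of chronic-care delivery in
a regional provider network. Five linked entities describe the system:

- **Demand**: a patient population partitioned into mutually exclusive
  *demand segments* — disease/treatment stages with homogeneous service
  needs. The bundled Type 2 Diabetes model distinguishes DS1 (at risk,
  screening), DS2 (lifestyle advice), DS3 (+ oral medication), DS4
  (+ insulin), DS5 (complicated, specialist care).
- **Services**: each segment receives one or more services per tenure
  phase; a service is a bundle of *service elements* (follow-up visit,
  lab test, diet consultation, …), each with a recommended annual
  frequency and a *utilization rate* — the fraction of patients who
  actually take the element up (no-show, non-adherence).
- **Structure**: resources (professionals, the laboratory, consumables)
  with a cost basis (per minute or per item) and a unit cost.
- **Behavior** and **outcomes**: per-segment profiles (smoking and
  drinking rates; satisfaction, self-rated health, HbA1c control) carried
  as declared data on their declared scales, never rescaled implicitly.

Disease progression is an annual discrete-time Markov chain over the
segments. Only leaving probabilities are stored; the stay probability is
implied as one minus their sum, which makes a row that sums away from 1
unrepresentable. States with no onward arcs (`exit`, and DS5 in the
bundled model, where care moves to the hospital) are absorbing.

### Tenure expansion

Segments whose service package changes with tenure (DS2: one diagnosis
year S2, then chronic treatment S3; DS4: one insulin-stabilization year
S5, then maintenance S6) are expanded into one state per tenure year up
to the open-ended final phase, which self-loops. Leaving probabilities
are identical across phases — progression risk is assumed
tenure-independent within a segment — so marginalizing the phases
recovers the original matrix row for row (a tested invariant). Sojourns
are therefore geometric with mean `1 / (total annual leave probability)`,
and all expected-journey quantities come from the fundamental matrix
`N = (I − T)⁻¹` of the absorbing chain, solved directly rather than
simulated.

### Activity-based costing

An element's annual cost per patient is
`frequency × utilization × per-delivery quantity × unit cost`, summed
over its required resources; services sum their elements; a segment-year
is a weighted mean of its phase services; a journey sums segment totals
weighted by sojourn years. Every result is a breakdown tree in which a
node's cost equals the sum of its children's costs exactly (in cents) —
conservation is enforced by construction and tested at every level.

Two conventions matter and are both explicit switches:

- **Quantity rounding** (`round_quantities`, default on): expected annual
  minutes/items per element are rounded half-up to whole units *before*
  pricing. This is the convention of the case-study tariff table (4.5
  expected dietician minutes bill as 5; 0.5 nurse minutes as 1) and is
  what makes S3 cost exactly €53.10 rather than the un-rounded €52.69.
- **Segment-cost mode**: `deterministic` weights phases by their share of
  the schedule's stated expected duration (DS2:
  (1 × 276.12 + 2 × 53.10)/3 = €127.44/year); `markov` weights phases by
  occupancy under the geometric sojourn (DS2: weight 0.375 on the
  diagnosis year, giving €136.73/year). The two disagree because the
  stated 3-year DS2 duration and the 2.667-year geometric mean implied by
  the transition row are themselves inconsistent; the package carries
  both and resolves neither. Deterministic is the default because it
  reproduces the published accounting.

Resources with no published unit cost (oral medication, insulin, test
kits, and several professionals) are *uncosted*: they contribute zero and
set a `partial` flag on every enclosing aggregate instead of being
silently treated as free. This is why the computed DS3/DS4 annual costs
are flagged partial and sit far below the published €419/€1666, which
include medication prices the model does not know.

### Cohort projection and rates

Entrants join at the start of a year, consume that year's services, and
transition at year end. `cohort_project` iterates this recurrence;
`steady_state_occupancy` solves the balance equations `x = e + xT`
directly and equals both the projection limit and, by Little's law,
incidence × expected visits (both tested). Incidence and prevalence are
straight ratios to population, rendered to two decimals as percent;
professional hours per patient-year are time-based (human) resource
minutes averaged over the schedule, to one decimal, with laboratory
minutes included by default (the convention that reproduces the
published DS2 value of 3.1 h; excluding lab gives 3.0).

## The microsimulation

The synthetic module is the stochastic oracle for every closed form.
Patients advance annually by sampling the expanded-chain rows; per
patient-year each element of the occupied state's service is delivered
all-or-nothing with probability equal to its utilization rate (count =
frequency when delivered), so the expected delivered count equals
frequency × utilization — exactly the deterministic engine's expectation.
A per-delivery Bernoulli variant with identical expectation and smaller
variance is available. Realized costs are priced without
expectation-rounding. A single `numpy` generator seeded explicitly makes
every output bit-reproducible; the tests check closed forms against
simulation means within 3 standard errors at n = 10⁵.

`estimate_transition_matrix` recovers segment-level rows by maximum
likelihood (observed movement frequencies over years at risk, tenure
phases marginalized), closing the generate → estimate consistency loop.

What the simulation does **not** emulate: individual covariates,
time-varying or tenure-dependent risks, correlated element uptake within
a patient-year, seasonal timing within years, or real outcome dispersion
(`sample_outcomes` uses an assumed truncated-normal spread of 10% of the
declared scale range, only to exercise reporting paths). Passing tests
therefore demonstrate internal consistency of the engine under its own
assumptions, not fidelity to any registry.

## The bundled T2D model

`build_t2d_fixture()` (identical to the shipped
`fixtures/t2d_nwn_dwo.yaml`, asserted in tests) encodes the Dutch
NWN&DWO-region case study: 20 service elements, services S1–S7, per-minute
tariffs (GP €1.10, lab €0.42, GP&nurse pair €0.71, dietician €0.53,
optometrist €1.10, practice nurse €0.29, diabetic nurse €0.58, lifestyle
consultant €0.58), segment schedules (DS2: 1 y S2 + open S3, expected
3 y; DS3: open S4, 9 y; DS4: 1 y S5 + open S6, 10 y), the DS2 transition
row (0.313 → DS3, 0.05 → DS5, 0.012 exit), 2009 region demand
(population 443,281; incidence 910; 12,218 prevalent patients with
observed counts DS2 2687 / DS3 8084 / DS4 1451), and the outcome and
behaviour profiles.

Choices made where the source data is silent or inconsistent:

- The DS3 and DS4 transition rows are not published. The fixture stores
  placeholders with total leave 1/9 and 1/10 (reciprocals of the stated
  9- and 10-year mean durations), split DS3 → {DS4: 1/9 − 0.02,
  DS5: 0.015, exit: 0.005} and DS4 → {DS5: 0.08, exit: 0.02}, and flags
  both rows `assumed_rows`.
- The "GP/Practice nurse" follow-up pair is a single composite resource
  priced €0.71/min, as the tariff table prices it.
- The published region-year column is internally inconsistent with its
  own per-patient totals (911 × €276.12 = €251,545.32, not €252,517);
  `region_annual_cost` computes the straight product.
- DS1 is modelled but not wired into the default transition chain
  (entrants are newly diagnosed patients entering DS2); DS5 is absorbing
  from the primary-care perspective but remains visible so referral
  volumes are reportable.
- SE2 (lab test in GP office) and SE15 (specialized care) have no
  assigned frequency in any primary-care service and are carried with
  zero usage.

## Numerical choices

- Currency is held as integer cents; fractional cents appear only where
  fractional weights (phase shares, sojourn years) multiply in above the
  element level. Rendering rounds cents half-up to two decimals.
- Half-up rounding is `floor(x + 0.5)` on non-negative quantities.
- Degenerate inputs: zero utilization or frequency give zero quantities;
  empty services cost €0; zero incidence gives an all-zero steady state;
  a state with zero total leave probability raises an immortal-state
  error from sojourn/steady-state code and is reported as a validation
  finding.
- Random models for property tests use 2–6 segments in a feed-forward
  chain, total leave probabilities in [0.05, 0.95], 1–5 elements per
  service, unit costs €0.10–€2.00/min, utilizations on a whole-percent
  grid; every failure is reproducible from the integer seed.
- Tests use simulation sizes of 10⁴–10⁵ patients with fixed seeds —
  large enough that 3-standard-error bands are tight (≲1% relative on
  the headline quantities) while the whole suite runs in seconds.

## Known limitations

No discounting or inflation; no age/sex stratification; no time-varying
matrices or competing risks beyond the annual chain; no travel/geography;
no inferential statistics on outcome differences; hospital care (S7) is
not elaborated. Table-level quantities that depend on unpublished
medication prices cannot be recomputed and are reported as observed data
with partial-cost flags.
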