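# carejourney

Patient-journey modelling for chronic care: demand segments, services
built from resource-consuming service elements, activity-based costing,
and an annual Markov cohort model over disease stages.

Chronic conditions such as Type 2 Diabetes progress through stages with
very different service needs. `carejourney` is for health-services
researchers and regional capacity planners who want to describe such a
system declaratively — *who* needs care (demand segments), *what* they
receive (services and elements with annual frequencies and utilization
rates), *with what* (resources and unit costs), and *how patients move*
(an annual transition matrix) — and then compute costs, resource loads,
patient-flow projections and journey-long outcomes from that single
definition. A complete Dutch Type 2 Diabetes case-study model is bundled.

## The model in brief

- **Costing** is activity-based: an element costs
  `frequency × utilization × minutes × tariff` summed over its resources
  (expected annual minutes rounded half-up to whole minutes before
  pricing, matching the case-study tariff tables); services, segment-years,
  and full journeys are exact sums/weighted means of their parts, and a
  node's cost always equals the sum of its children's costs in cents.
  Resources without a published price (e.g. medication) contribute zero
  and raise a `partial` flag rather than passing silently as free.
- **Progression** is an annual Markov chain over segments with implied
  stay probabilities and absorbing states. Multi-phase segments (a first
  diagnosis or insulin-stabilization year, then maintenance) are expanded
  into tenure states. Mean sojourn in a segment is
  `1 / Σ(leave probabilities)`; expected years per state come from the
  absorbing-chain fundamental matrix `N = (I − T)⁻¹`; steady-state
  occupancy equals `incidence × N` (Little's law).
- **Microsimulation** realizes individual trajectories and Bernoulli
  service uptake under a fixed seed and serves as the stochastic oracle
  for every closed form.

See `docs/methods.md` for assumptions, conventions and limitations.

## Worked example

```python
import carejourney as cj

model = cj.load_model(cj.t2d_fixture_path())

cj.service_annual_cost("S2", model).cost_eur    # 276.12  (diagnosis year)
cj.service_annual_cost("S3", model).cost_eur    # 53.1    (chronic treatment)
cj.segment_annual_cost("DS2", model).cost_eur   # 127.44  (1y S2 + 2y S3, averaged)
cj.professional_hours("DS2", model)             # 3.1     (hours/patient-year)
cj.mean_sojourn(model.transitions, "DS2")       # 2.6666... years

occ = cj.steady_state_occupancy(model, {"DS2": 910})
sum(v for k, v in occ.items() if k.startswith("DS2"))   # 2426.67 patients
```

Reading: a newly diagnosed patient costs €276.12 in the diagnosis year
and €53.10 per chronic-treatment year, i.e. €127.44 per year averaged
over an expected 3-year stay in the lifestyle-advice stage, during which
they receive 3.1 hours of professional care per year. The transition
probabilities out of that stage (0.313 + 0.05 + 0.012) imply a mean
sojourn of 2.67 years, so a constant inflow of 910 newly diagnosed
patients per year sustains about 2,427 patients in the stage.

The same is available from the shell:

```sh
carejourney validate src/carejourney/fixtures/t2d_nwn_dwo.yaml
carejourney cost src/carejourney/fixtures/t2d_nwn_dwo.yaml --service S2
carejourney project src/carejourney/fixtures/t2d_nwn_dwo.yaml --incidence 910 --horizon 30 -o occupancy.csv
carejourney simulate src/carejourney/fixtures/t2d_nwn_dwo.yaml --n 1000 --horizon 50 --seed 7 -o trajectories.csv
carejourney report src/carejourney/fixtures/t2d_nwn_dwo.yaml -o report.csv
```

## Defining your own model

A model is a single YAML file with sections `metadata`, `resources`,
`elements`, `services`, `segments`, `transitions`, `region`. Unit costs
are written in currency units (two decimals), utilizations in percent;
transition rows list only leaving probabilities (staying is implied).
Start from `src/carejourney/fixtures/t2d_nwn_dwo.yaml` and change or add
services and resources; `carejourney validate` reports every referential
or probabilistic inconsistency as a named finding.
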