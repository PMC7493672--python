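"""Resource-requirement, rate and outcome aggregation.

Turns the per-element expected quantities into the summaries a regional
planner reads: professional-care hours per patient-year, resource loads
for a given occupancy, incidence/prevalence rates, journey-long outcome
totals, and the per-segment results table (patients, hours, cost, and the
observed outcome/behaviour profiles).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Mapping, Optional

import pandas as pd

from . import cohort, costing
from .schema import ModelDefinition, RegionDemand

__all__ = [
    "ResourceLoad",
    "RateReport",
    "JourneyOutcome",
    "professional_hours",
    "resource_load",
    "rates",
    "journey_outcome",
    "segment_report",
]


def _service_minutes_by_resource(
    model: ModelDefinition,
    service_id: str,
    *,
    include_lab: bool = True,
    include_items: bool = False,
    round_quantities: bool = True,
) -> dict[str, float]:
    """Expected annual quantity per resource for one service.  Per-minute
    resources of kind ``human`` always count; kinds ``facility``/``device``
    (the laboratory) only when ``include_lab``; per-item resources only
    when ``include_items``."""
    out: dict[str, float] = {}
    service = model.service(service_id)
    for usage in service.usages:
        element = model.element(usage.element)
        for req in element.requirements:
            res = model.resource(req.resource)
            if res.cost_basis == "per_item":
                if not include_items:
                    continue
            elif res.kind != "human" and not include_lab:
                continue
            q = costing.expected_annual_quantity(
                usage, element, req.resource, round_quantities=round_quantities
            )
            out[res.id] = out.get(res.id, 0.0) + q
    return out


def professional_hours(
    segment: str,
    model: ModelDefinition,
    *,
    include_lab: bool = True,
    round_quantities: bool = True,
) -> float:
    """Hours of professional care per patient per year in one segment:
    time-based resource minutes summed over the scheduled years, averaged
    over the expected total duration, divided by 60 and reported to one
    decimal.  ``include_lab`` controls whether laboratory (non-human,
    per-minute) resources count as professional care."""
    seg = model.segment(segment)
    if seg.schedule is None:
        raise ValueError(f"segment {segment!r} has no schedule")
    phase_years = seg.schedule.resolved_phase_years()
    total_years = sum(y for _, y in phase_years)
    minutes = 0.0
    for sid, years in phase_years:
        per_year = _service_minutes_by_resource(
            model, sid, include_lab=include_lab, round_quantities=round_quantities
        )
        minutes += years * sum(per_year.values())
    return round(minutes / total_years / 60, 1)


@dataclass
class ResourceLoad:
    """Expected annual quantity per resource (minutes or items), at region
    level for a given occupancy.  Additive over states and linear in the
    occupancy counts."""

    quantities: dict[str, float]
    units: dict[str, str]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"resource": rid, "quantity": q, "unit": self.units[rid]}
                for rid, q in self.quantities.items()
            ]
        )


def _occupancy_service(model: ModelDefinition, key: str) -> str:
    """Resolve an occupancy key (service id, expanded-state label
    ``SEG:phase``, or single-phase segment id) to the service received."""
    if any(s.id == key for s in model.services):
        return key
    if ":" in key:
        chain = cohort.expand_tenure(model)
        return chain.state(key).service
    seg = model.segment(key)
    if seg.schedule is None or len({p.service for p in seg.schedule.phases}) != 1:
        raise ValueError(
            f"occupancy key {key!r} is a multi-phase segment; use 'SEG:phase' labels"
        )
    return seg.schedule.phases[0].service


def resource_load(
    model: ModelDefinition,
    occupancy: Mapping[str, float],
    *,
    round_quantities: bool = True,
) -> ResourceLoad:
    """Region-level resource requirements: for each resource, the sum over
    occupied states of patient count times per-patient-year quantity under
    the state's service.  Keys of ``occupancy`` may be service ids,
    expanded-state labels (``DS2:1``) or single-phase segment ids."""
    quantities: dict[str, float] = {}
    units: dict[str, str] = {}
    for key, n in occupancy.items():
        sid = _occupancy_service(model, key)
        per_patient = _service_minutes_by_resource(
            model,
            sid,
            include_lab=True,
            include_items=True,
            round_quantities=round_quantities,
        )
        for rid, q in per_patient.items():
            quantities[rid] = quantities.get(rid, 0.0) + n * q
            units[rid] = model.resource(rid).quantity_unit
    return ResourceLoad(quantities, units)


@dataclass
class RateReport:
    """Incidence and prevalence as fractions, with denominators recorded;
    percent renderings use two decimals."""

    incidence: float
    prevalence: float
    population: int
    new_patients: int
    total_patients: int

    @property
    def incidence_pct(self) -> float:
        return round(self.incidence * 100, 2)

    @property
    def prevalence_pct(self) -> float:
        return round(self.prevalence * 100, 2)


def rates(region: RegionDemand, total_patients: int) -> RateReport:
    """Annual incidence rate (new patients / population) and prevalence
    (total patients / population)."""
    if region.population <= 0:
        raise ValueError("population must be > 0")
    return RateReport(
        incidence=region.annual_incidence / region.population,
        prevalence=total_patients / region.population,
        population=region.population,
        new_patients=region.annual_incidence,
        total_patients=total_patients,
    )


@dataclass
class JourneyOutcome:
    """Sojourn-weighted outcome over a full expected journey."""

    outcome: str
    total: float
    years: float

    @property
    def mean_per_year(self) -> float:
        return self.total / self.years


def journey_outcome(
    model: ModelDefinition,
    entry_segment: str,
    outcome: str,
    mode: Literal["markov", "deterministic"] = "markov",
) -> JourneyOutcome:
    """Expected sojourn-weighted total of one outcome over the journey
    entering at ``entry_segment``: the sum over visited segments of
    expected years times the segment's per-year outcome value."""
    if mode == "markov":
        years_by_segment = cohort.expected_years_by_segment(model, entry_segment)
    elif mode == "deterministic":
        years_by_segment = {}
        for sid in costing._deterministic_pathway(model, entry_segment):
            seg = model.segment(sid)
            if seg.schedule is None or seg.schedule.expected_total_duration is None:
                raise ValueError(f"segment {sid!r} has no expected_total_duration")
            years_by_segment[sid] = float(seg.schedule.expected_total_duration)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    total = 0.0
    years = 0.0
    for sid, y in years_by_segment.items():
        if y <= 0:
            continue
        seg = model.segment(sid)
        if outcome not in seg.outcomes:
            raise KeyError(
                f"segment {sid!r} is reachable but carries no outcome {outcome!r}"
            )
        total += y * seg.outcomes[outcome]
        years += y
    return JourneyOutcome(outcome=outcome, total=total, years=years)


def segment_report(
    model: ModelDefinition,
    *,
    include_lab: bool = True,
    mode: Literal["deterministic", "markov"] = "deterministic",
    round_quantities: bool = True,
) -> pd.DataFrame:
    """Per-segment results table: observed patient count, professional
    hours per patient-year, cost per patient-year (with partial-cost
    flag), and the pass-through outcome/behaviour profile columns."""
    counts = (
        model.region.observed_segment_counts if model.region is not None else {}
    )
    rows = []
    for seg in model.segments:
        if seg.schedule is None:
            continue
        cost = costing.segment_annual_cost(
            seg.id, model, mode, round_quantities=round_quantities
        )
        row: dict[str, object] = {
            "segment": seg.id,
            "n_patients": counts.get(seg.id),
            "hours_per_patient_year": professional_hours(
                seg.id, model, include_lab=include_lab, round_quantities=round_quantities
            ),
            "cost_per_patient_year": cost.cost_eur,
            "partial_cost_flag": cost.partial,
        }
        row.update(seg.outcomes)
        row.update(seg.behavior)
        rows.append(row)
    return pd.DataFrame(rows)
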