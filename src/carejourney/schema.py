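"""Domain types for the five-entity care-network model.

The model describes a regional chronic-care provider network through five
linked entities: *demand* (a population partitioned into demand segments),
*services* (each a bundle of service elements with annual frequencies and
utilization rates), *structure* (resources with unit costs), *behavior*
(per-segment behaviour profiles such as smoking rates) and *outcomes*
(per-segment outcome profiles such as satisfaction scores).  A discrete-time
transition matrix over the demand segments describes disease progression.

All types are pydantic models so that construction performs type and range
checking and serialization round-trips are lossless.  Cross-reference
invariants (dangling ids, transition-row consistency, outcome scales) are
checked by :func:`validate_model`, which reports findings as data rather
than raising, so that any syntactically parseable configuration yields
either a model or a finite list of findings.

Conventions: currency is held internally as integer cents per basis unit;
utilization rates are held internally as fractions in [0, 1] (the config
file uses percent).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional

from pydantic import BaseModel, Field

ResourceKind = Literal["human", "device", "facility", "consumable"]
CostBasis = Literal["per_minute", "per_item"]

#: absorbing state present in every transition model
EXIT_STATE = "exit"


class Resource(BaseModel):
    """A means to provide a service: a professional, device, facility or
    consumable, priced per minute or per item.  ``unit_cost_cents is None``
    marks the resource as *uncosted* (no tariff known); any cost aggregate
    it contributes to carries a partial-cost flag."""

    id: str
    name: str = ""
    kind: ResourceKind = "human"
    cost_basis: CostBasis = "per_minute"
    unit_cost_cents: Optional[int] = Field(default=None, ge=0)

    @property
    def uncosted(self) -> bool:
        return self.unit_cost_cents is None

    @property
    def quantity_unit(self) -> str:
        return "min" if self.cost_basis == "per_minute" else "item"


class ResourceRequirement(BaseModel):
    """Quantity of one resource consumed by a single delivery of a service
    element, in the resource's basis unit (minutes or items)."""

    resource: str
    quantity: float = Field(gt=0)


class ServiceElement(BaseModel):
    """The atomic unit of service delivery (e.g. a follow-up visit)."""

    id: str
    name: str = ""
    requirements: list[ResourceRequirement] = Field(default_factory=list)


class ServiceElementUsage(BaseModel):
    """How a demand segment uses one service element: recommended
    deliveries per patient-year and the fraction of patients who actually
    take them up (captures no-show and non-adherence)."""

    element: str
    frequency: float = Field(ge=0)
    utilization: float = Field(default=1.0, ge=0, le=1)


class Service(BaseModel):
    """A service journey: the set of service elements delivered annually to
    one demand segment."""

    id: str
    name: str = ""
    usages: list[ServiceElementUsage] = Field(default_factory=list)


class SchedulePhase(BaseModel):
    """One tenure phase of a segment's schedule: a service received for a
    fixed number of whole years, or open-ended (``years is None``, only
    legal for the final phase)."""

    service: str
    years: Optional[int] = Field(default=None, ge=1)


class SegmentSchedule(BaseModel):
    """Tenure-phased mapping of a demand segment to services, e.g. one year
    of a diagnosis service followed by open-ended chronic treatment.
    ``expected_total_duration`` is the mean years spent in the segment used
    for deterministic accounting."""

    phases: list[SchedulePhase]
    expected_total_duration: Optional[int] = Field(default=None, ge=1)

    def resolved_phase_years(self, total: Optional[int] = None) -> list[tuple[str, int]]:
        """Return (service id, whole years) per phase with the open-ended
        final phase resolved against ``total`` (defaults to
        ``expected_total_duration``)."""
        total = total if total is not None else self.expected_total_duration
        closed = sum(p.years for p in self.phases if p.years is not None)
        out: list[tuple[str, int]] = []
        for p in self.phases:
            if p.years is not None:
                out.append((p.service, p.years))
            else:
                if total is None:
                    raise ValueError(
                        "open-ended phase requires expected_total_duration"
                    )
                out.append((p.service, total - closed))
        return out


class DemandSegment(BaseModel):
    """A mutually exclusive subset of the patient population with a common
    demand for services — here, a disease/treatment stage."""

    id: str
    name: str = ""
    schedule: Optional[SegmentSchedule] = None
    outcomes: dict[str, float] = Field(default_factory=dict)
    behavior: dict[str, float] = Field(default_factory=dict)


class TransitionModel(BaseModel):
    """Annual stochastic matrix over demand segments.

    ``rows`` stores only the *leave* probabilities per non-absorbing state;
    the stay probability is implied as one minus their sum, so a row can
    never accidentally sum away from 1.  ``assumed_rows`` marks rows whose
    probabilities are documented placeholders rather than observed data.
    """

    absorbing: list[str] = Field(default_factory=lambda: [EXIT_STATE])
    rows: dict[str, dict[str, float]] = Field(default_factory=dict)
    assumed_rows: list[str] = Field(default_factory=list)

    @property
    def states(self) -> list[str]:
        return list(self.rows) + [s for s in self.absorbing if s not in self.rows]

    def leave_sum(self, state: str) -> float:
        return float(sum(self.rows[state].values()))

    def stay(self, state: str) -> float:
        return 1.0 - self.leave_sum(state)


class RegionDemand(BaseModel):
    """Demand side of one region: population, annual incidence of newly
    diagnosed patients, and optionally the observed patient count per
    segment (registry data, carried as-is)."""

    population: int = Field(ge=0)
    annual_incidence: int = Field(ge=0)
    observed_segment_counts: dict[str, int] = Field(default_factory=dict)


class Metadata(BaseModel):
    name: str = ""
    currency: str = "EUR"
    year: Optional[int] = None
    entry_segment: Optional[str] = None
    outcome_scales: dict[str, tuple[float, float]] = Field(default_factory=dict)
    notes: str = ""


class ModelDefinition(BaseModel):
    """The complete declarative model: resources, elements, services,
    segments, transitions and region demand."""

    metadata: Metadata = Field(default_factory=Metadata)
    resources: list[Resource] = Field(default_factory=list)
    elements: list[ServiceElement] = Field(default_factory=list)
    services: list[Service] = Field(default_factory=list)
    segments: list[DemandSegment] = Field(default_factory=list)
    transitions: TransitionModel = Field(default_factory=TransitionModel)
    region: Optional[RegionDemand] = None

    # -- lookups -------------------------------------------------------
    def resource(self, rid: str) -> Resource:
        return _lookup(self.resources, rid, "resource")

    def element(self, eid: str) -> ServiceElement:
        return _lookup(self.elements, eid, "element")

    def service(self, sid: str) -> Service:
        return _lookup(self.services, sid, "service")

    def segment(self, gid: str) -> DemandSegment:
        return _lookup(self.segments, gid, "segment")

    @property
    def entry_segment(self) -> str:
        if self.metadata.entry_segment:
            return self.metadata.entry_segment
        if self.transitions.rows:
            return next(iter(self.transitions.rows))
        raise ValueError("model has no transition rows and no entry_segment")


def _lookup(items, key: str, what: str):
    for it in items:
        if it.id == key:
            return it
    raise KeyError(f"unknown {what} id: {key!r}")


# ----------------------------------------------------------------------
# Validation
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class Finding:
    """A single validation finding: machine code, offending location and a
    human-readable message.  Findings are data, not exceptions."""

    code: str
    where: str
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"[{self.code}] {self.where}: {self.message}"


class ModelFormatError(Exception):
    """Raised when a config file cannot be parsed at all."""


class ModelValidationError(Exception):
    """Raised by strict loading when a parseable config violates model
    invariants; carries the list of findings."""

    def __init__(self, findings: list[Finding]):
        self.findings = findings
        super().__init__(
            "; ".join(str(f) for f in findings) or "invalid model"
        )


_ROW_SUM_TOL = 1e-9


def _check_unique(items, what: str, findings: list[Finding]) -> None:
    seen: set[str] = set()
    for it in items:
        if it.id in seen:
            findings.append(Finding("duplicate-id", f"{what} {it.id}", f"duplicate {what} id"))
        seen.add(it.id)


def validate_transitions(t: TransitionModel) -> list[Finding]:
    """Check the transition-matrix invariants.

    Returns an empty list iff all probabilities lie in [0, 1], every row's
    leave probabilities sum to at most 1, every target is a known state,
    and every non-absorbing state has a positive-probability path to an
    absorbing state (no immortal cohort).
    """
    findings: list[Finding] = []
    known = set(t.rows) | set(t.absorbing)
    for state, row in t.rows.items():
        if state in t.absorbing:
            findings.append(Finding("absorbing-row", state, "absorbing state has a transition row"))
        for target, p in row.items():
            if target not in known:
                findings.append(Finding("dangling-ref", f"{state}->{target}", "unknown target state"))
            if not 0.0 <= p <= 1.0:
                findings.append(Finding("bad-probability", f"{state}->{target}", f"probability {p} outside [0, 1]"))
            if target == state:
                findings.append(Finding("explicit-stay", state, "stay probability must be implied, not stored"))
        s = t.leave_sum(state)
        if s > 1.0 + _ROW_SUM_TOL:
            findings.append(Finding("row-exceeds-1", state, f"leave probabilities sum to {s:.6g} > 1"))
    # reachability of absorption through positive-probability arcs
    reaches: set[str] = set(t.absorbing)
    changed = True
    while changed:
        changed = False
        for state, row in t.rows.items():
            if state in reaches:
                continue
            if any(p > 0 and tgt in reaches for tgt, p in row.items()):
                reaches.add(state)
                changed = True
    for state in t.rows:
        if state not in reaches and state not in t.absorbing:
            findings.append(Finding("immortal-state", state, "no positive-probability path to an absorbing state"))
    return findings


def validate_model(m: ModelDefinition) -> list[Finding]:
    """Check referential integrity and value invariants across the whole
    model; returns an empty list iff the model is valid."""
    findings: list[Finding] = []
    _check_unique(m.resources, "resource", findings)
    _check_unique(m.elements, "element", findings)
    _check_unique(m.services, "service", findings)
    _check_unique(m.segments, "segment", findings)

    resource_ids = {r.id for r in m.resources}
    element_ids = {e.id for e in m.elements}
    service_ids = {s.id for s in m.services}
    segment_ids = {g.id for g in m.segments}

    for e in m.elements:
        for req in e.requirements:
            if req.resource not in resource_ids:
                findings.append(Finding("dangling-ref", f"element {e.id}", f"unknown resource {req.resource!r}"))

    for s in m.services:
        seen: set[str] = set()
        for u in s.usages:
            if u.element not in element_ids:
                findings.append(Finding("dangling-ref", f"service {s.id}", f"unknown element {u.element!r}"))
            if u.element in seen:
                findings.append(Finding("duplicate-usage", f"service {s.id}", f"element {u.element} listed twice"))
            seen.add(u.element)

    for g in m.segments:
        if g.schedule is not None:
            sched = g.schedule
            for i, p in enumerate(sched.phases):
                if p.service not in service_ids:
                    findings.append(Finding("dangling-ref", f"segment {g.id}", f"unknown service {p.service!r}"))
                if p.years is None and i != len(sched.phases) - 1:
                    findings.append(Finding("open-phase-not-last", f"segment {g.id}", "open-ended phase must be the final phase"))
            closed = sum(p.years for p in sched.phases if p.years is not None)
            if sched.expected_total_duration is not None and closed > sched.expected_total_duration:
                findings.append(Finding(
                    "schedule-overrun", f"segment {g.id}",
                    f"closed phases span {closed} y > expected total {sched.expected_total_duration} y"))
        for name, value in g.outcomes.items():
            scale = m.metadata.outcome_scales.get(name)
            if scale is not None and not scale[0] <= value <= scale[1]:
                findings.append(Finding(
                    "outcome-out-of-scale", f"segment {g.id}",
                    f"outcome {name}={value} outside declared scale {scale}"))

    for state in m.transitions.rows:
        if state not in segment_ids:
            findings.append(Finding("dangling-ref", f"transitions {state}", "row for unknown segment"))
    for state, row in m.transitions.rows.items():
        for target in row:
            if target not in segment_ids and target not in m.transitions.absorbing:
                findings.append(Finding("dangling-ref", f"{state}->{target}", "target is neither a segment nor absorbing"))
    findings.extend(validate_transitions(m.transitions))

    if m.region is not None and m.region.annual_incidence > m.region.population:
        findings.append(Finding("incidence-exceeds-population", "region", "annual incidence exceeds population"))
    if m.metadata.entry_segment and m.metadata.entry_segment not in segment_ids:
        findings.append(Finding("dangling-ref", "metadata.entry_segment", f"unknown segment {m.metadata.entry_segment!r}"))
    return findings
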