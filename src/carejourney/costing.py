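"""Activity-based costing of patient journeys.

Each service element is priced as the sum of its resource usages times the
resource unit costs; services sum their elements; segment-years are
time-weighted means over the tenure phases of the segment's schedule; a
full journey sums segment totals weighted by expected sojourn years.  The
result at every level is a :class:`CostBreakdown` tree in which a node's
cost is exactly the sum of its children's costs (in cents).

Expected annual quantities per element are rounded half-up to whole basis
units (minutes or items) *before* pricing by default — the convention the
bundled case-study tariffs are quoted in (e.g. 4.5 expected minutes of
dietician time is billed as 5).  Pass ``round_quantities=False`` for the
un-rounded closed form ``frequency x utilization x per-delivery quantity``.

Resources without a unit cost contribute zero cost and set the ``partial``
flag on every enclosing node rather than being silently treated as free.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterator, Literal, Optional

import pandas as pd

from .schema import (
    ModelDefinition,
    Resource,
    Service,
    ServiceElement,
    ServiceElementUsage,
)

Level = Literal[
    "resource", "element", "service", "segment_year", "segment_total", "journey", "region"
]


def round_half_up(x: float) -> int:
    """Round a non-negative quantity half-up to a whole unit (4.5 -> 5)."""
    return int(math.floor(x + 0.5))


@dataclass
class CostBreakdown:
    """One node of a hierarchical cost result.

    ``cost`` is in integer-cent units (float-valued only where fractional
    weights enter above the element level); ``expected_quantity`` is in the
    node's ``unit`` per patient-year at element/resource level, scaled by
    the enclosing weights above that.  ``partial`` is true when any
    uncosted resource contributes anywhere below this node.
    """

    level: Level
    id: str
    name: str = ""
    expected_quantity: Optional[float] = None
    unit: Optional[str] = None
    unit_cost_cents: Optional[int] = None
    cost: float = 0.0
    partial: bool = False
    children: list["CostBreakdown"] = field(default_factory=list)

    @property
    def cost_eur(self) -> float:
        """Cost in currency units, cents rounded half-up for rendering."""
        return round_half_up(self.cost) / 100

    def walk(self) -> Iterator["CostBreakdown"]:
        yield self
        for c in self.children:
            yield from c.walk()

    def to_frame(self) -> pd.DataFrame:
        """Flatten the tree depth-first into the standard tabular layout."""
        rows = [
            {
                "level": n.level,
                "id": n.id,
                "name": n.name,
                "expected_quantity": n.expected_quantity,
                "unit": n.unit,
                "unit_cost": None if n.unit_cost_cents is None else n.unit_cost_cents / 100,
                "cost": n.cost_eur,
                "partial": n.partial,
            }
            for n in self.walk()
        ]
        return pd.DataFrame(rows)


def _scale(node: CostBreakdown, factor: float) -> CostBreakdown:
    """Scale a breakdown subtree by ``factor``, recomputing every internal
    cost as the sum of its scaled children so conservation stays exact."""
    children = [_scale(c, factor) for c in node.children]
    cost = sum(c.cost for c in children) if children else node.cost * factor
    qty = None if node.expected_quantity is None else node.expected_quantity * factor
    return replace(node, cost=cost, expected_quantity=qty, children=children)


# ----------------------------------------------------------------------
# Element level
# ----------------------------------------------------------------------

def expected_annual_quantity(
    usage: ServiceElementUsage,
    element: ServiceElement,
    resource_id: str,
    *,
    round_quantities: bool = True,
) -> float:
    """Expected annual consumption of one resource by one element usage:
    frequency x utilization x per-delivery quantity, rounded half-up to a
    whole basis unit unless ``round_quantities`` is off."""
    if usage.element != element.id:
        raise ValueError(f"usage references {usage.element!r}, not element {element.id!r}")
    for req in element.requirements:
        if req.resource == resource_id:
            q = usage.frequency * usage.utilization * req.quantity
            return float(round_half_up(q)) if round_quantities else q
    raise KeyError(f"element {element.id!r} does not require resource {resource_id!r}")


def element_annual_cost(
    usage: ServiceElementUsage,
    model: ModelDefinition,
    *,
    round_quantities: bool = True,
) -> CostBreakdown:
    """Expected annual cost of one element usage: the sum over the
    element's required resources of expected quantity x unit cost."""
    element = model.element(usage.element)
    children: list[CostBreakdown] = []
    for req in element.requirements:
        res: Resource = model.resource(req.resource)
        qty = expected_annual_quantity(
            usage, element, req.resource, round_quantities=round_quantities
        )
        cost = 0.0 if res.uncosted else qty * res.unit_cost_cents
        children.append(
            CostBreakdown(
                level="resource",
                id=res.id,
                name=res.name,
                expected_quantity=qty,
                unit=res.quantity_unit,
                unit_cost_cents=res.unit_cost_cents,
                cost=cost,
                partial=res.uncosted,
            )
        )
    node = CostBreakdown(
        level="element",
        id=element.id,
        name=element.name,
        cost=sum(c.cost for c in children),
        partial=any(c.partial for c in children),
        children=children,
    )
    # single-resource elements surface their quantity directly (the common case)
    if len(children) == 1:
        node.expected_quantity = children[0].expected_quantity
        node.unit = children[0].unit
        node.unit_cost_cents = children[0].unit_cost_cents
    return node


# ----------------------------------------------------------------------
# Service and segment level
# ----------------------------------------------------------------------

def service_annual_cost(
    service: Service | str,
    model: ModelDefinition,
    *,
    round_quantities: bool = True,
) -> CostBreakdown:
    """Expected per-patient annual cost of one service: the sum of its
    element-level costs, children retained."""
    if isinstance(service, str):
        service = model.service(service)
    children = [
        element_annual_cost(u, model, round_quantities=round_quantities)
        for u in service.usages
    ]
    return CostBreakdown(
        level="service",
        id=service.id,
        name=service.name,
        cost=sum(c.cost for c in children),
        partial=any(c.partial for c in children),
        children=children,
    )


def segment_annual_cost(
    segment: str,
    model: ModelDefinition,
    mode: Literal["deterministic", "markov"] = "deterministic",
    *,
    round_quantities: bool = True,
) -> CostBreakdown:
    """Expected cost per patient-year in one demand segment.

    Deterministic mode weights each tenure phase's service by its share of
    the schedule's expected total duration (the accounting the case-study
    tables use).  Markov mode instead weights phases by their occupancy
    share under the geometric sojourn implied by the transition matrix:
    the expected years spent in each tenure phase divided by the total
    expected sojourn.
    """
    seg = model.segment(segment)
    if seg.schedule is None:
        raise ValueError(f"segment {segment!r} has no schedule")
    weights: list[tuple[str, float]]
    if mode == "deterministic":
        phase_years = seg.schedule.resolved_phase_years()
        total = sum(y for _, y in phase_years)
        weights = [(sid, y / total) for sid, y in phase_years]
    elif mode == "markov":
        from .cohort import expand_tenure, expected_visits

        chain = expand_tenure(model)
        visits = expected_visits(model, segment, chain=chain)
        total = sum(
            v for st, v in visits.items() if chain.state(st).segment == segment
        )
        per_service: dict[str, float] = {}
        for st, v in visits.items():
            xs = chain.state(st)
            if xs.segment == segment:
                per_service[xs.service] = per_service.get(xs.service, 0.0) + v
        weights = [(sid, v / total) for sid, v in per_service.items()]
    else:
        raise ValueError(f"unknown mode {mode!r}")
    children = [
        _scale(service_annual_cost(sid, model, round_quantities=round_quantities), w)
        for sid, w in weights
    ]
    return CostBreakdown(
        level="segment_year",
        id=seg.id,
        name=seg.name,
        cost=sum(c.cost for c in children),
        partial=any(c.partial for c in children),
        children=children,
    )


def _deterministic_pathway(model: ModelDefinition, start: str) -> list[str]:
    """The printed pathway: from each segment follow the most probable
    onward movement to a non-absorbing segment, visiting each at most once."""
    path = [start]
    current = start
    while True:
        row = model.transitions.rows.get(current, {})
        nxt = None
        best = 0.0
        for target, p in row.items():
            if p > best and target in model.transitions.rows and target not in path:
                nxt, best = target, p
        if nxt is None:
            return path
        path.append(nxt)
        current = nxt


def journey_cost(
    model: ModelDefinition,
    start: str,
    mode: Literal["deterministic", "markov"] = "deterministic",
    *,
    round_quantities: bool = True,
) -> CostBreakdown:
    """Expected total cost of a complete service user journey entering at
    ``start``: the sum over segments of expected sojourn years times the
    segment's annual cost.

    Deterministic mode walks the main pathway and uses each segment's
    expected total duration; markov mode uses the absorbing-chain expected
    years per segment.
    """
    children: list[CostBreakdown] = []
    if mode == "deterministic":
        for sid in _deterministic_pathway(model, start):
            seg = model.segment(sid)
            if seg.schedule is None:
                continue
            years = seg.schedule.expected_total_duration
            if years is None:
                raise ValueError(f"segment {sid!r} has no expected_total_duration")
            per_year = segment_annual_cost(
                sid, model, "deterministic", round_quantities=round_quantities
            )
            node = _scale(per_year, float(years))
            node = replace(node, level="segment_total")
            children.append(node)
    elif mode == "markov":
        from .cohort import expand_tenure, expected_visits

        chain = expand_tenure(model)
        visits = expected_visits(model, start, chain=chain)
        by_segment: dict[str, dict[str, float]] = {}
        for st, years in visits.items():
            xs = chain.state(st)
            by_segment.setdefault(xs.segment, {})
            by_segment[xs.segment][xs.service] = (
                by_segment[xs.segment].get(xs.service, 0.0) + years
            )
        for sid, services in by_segment.items():
            seg = model.segment(sid)
            parts = [
                _scale(
                    service_annual_cost(svc, model, round_quantities=round_quantities),
                    years,
                )
                for svc, years in services.items()
                if years > 0
            ]
            children.append(
                CostBreakdown(
                    level="segment_total",
                    id=sid,
                    name=seg.name,
                    cost=sum(p.cost for p in parts),
                    partial=any(p.partial for p in parts),
                    children=parts,
                )
            )
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return CostBreakdown(
        level="journey",
        id=start,
        name=f"journey from {start}",
        cost=sum(c.cost for c in children),
        partial=any(c.partial for c in children),
        children=children,
    )


def region_annual_cost(
    model: ModelDefinition,
    n_patients: float,
    *,
    service: Optional[str] = None,
    segment: Optional[str] = None,
    mode: Literal["deterministic", "markov"] = "deterministic",
    round_quantities: bool = True,
) -> CostBreakdown:
    """Region-level annual cost: n patients times the per-patient annual
    cost of one service or one segment, cents-exact."""
    if (service is None) == (segment is None):
        raise ValueError("give exactly one of service= or segment=")
    if n_patients < 0:
        raise ValueError("n_patients must be >= 0")
    if service is not None:
        per_patient = service_annual_cost(service, model, round_quantities=round_quantities)
    else:
        per_patient = segment_annual_cost(
            segment, model, mode, round_quantities=round_quantities
        )
    node = _scale(per_patient, float(n_patients))
    return CostBreakdown(
        level="region",
        id=per_patient.id,
        name=f"{per_patient.id} x {n_patients:g} patients",
        cost=node.cost,
        partial=node.partial,
        children=[node],
    )
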