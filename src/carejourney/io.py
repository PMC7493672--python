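"""Read and write model definitions as YAML.

The config file mirrors the five framework entities with top-level sections
``metadata``, ``resources``, ``elements``, ``services``, ``segments``,
``transitions`` and ``region``.  External conventions differ from the
in-memory ones in two places:

* ``unit_cost`` is written in currency units with two decimals (e.g.
  ``1.10`` EUR per minute) and held internally as integer cents;
* ``utilization`` is written in percent (e.g. ``80``) and held internally
  as a fraction.

Round-trips through :func:`save_model` / :func:`load_model` are lossless
field-for-field, including the uncosted flag (an absent ``unit_cost``) and
the ``assumed_rows`` annotation on placeholder transition rows.
"""

from __future__ import annotations

import os
from typing import Any, Optional

import yaml

from .schema import (
    DemandSegment,
    Metadata,
    ModelDefinition,
    ModelFormatError,
    ModelValidationError,
    RegionDemand,
    Resource,
    ResourceRequirement,
    SchedulePhase,
    SegmentSchedule,
    Service,
    ServiceElement,
    ServiceElementUsage,
    TransitionModel,
    validate_model,
)

__all__ = ["load_model", "save_model", "model_to_dict", "model_from_dict"]


def _cents(value: Optional[float]) -> Optional[int]:
    if value is None:
        return None
    cents = round(float(value) * 100)
    if abs(cents - float(value) * 100) > 1e-6:
        raise ValueError(f"unit cost {value!r} has sub-cent precision")
    return int(cents)


def _eur(cents: Optional[int]) -> Optional[float]:
    return None if cents is None else cents / 100


def model_from_dict(doc: dict[str, Any]) -> ModelDefinition:
    """Build a ModelDefinition from a parsed config mapping (no
    cross-reference validation; see :func:`carejourney.schema.validate_model`)."""
    if not isinstance(doc, dict):
        raise ModelFormatError("top level of a model file must be a mapping")

    meta_doc = dict(doc.get("metadata") or {})
    scales = {
        k: tuple(v) for k, v in (meta_doc.pop("outcome_scales", None) or {}).items()
    }
    metadata = Metadata(outcome_scales=scales, **meta_doc)

    resources = [
        Resource(
            id=r["id"],
            name=r.get("name", ""),
            kind=r.get("kind", "human"),
            cost_basis=r.get("cost_basis", "per_minute"),
            unit_cost_cents=_cents(r.get("unit_cost")),
        )
        for r in doc.get("resources") or []
    ]
    elements = [
        ServiceElement(
            id=e["id"],
            name=e.get("name", ""),
            requirements=[
                ResourceRequirement(resource=q["resource"], quantity=q["quantity"])
                for q in e.get("requires") or []
            ],
        )
        for e in doc.get("elements") or []
    ]
    services = [
        Service(
            id=s["id"],
            name=s.get("name", ""),
            usages=[
                ServiceElementUsage(
                    element=u["element"],
                    frequency=u["frequency"],
                    utilization=float(u.get("utilization", 100)) / 100,
                )
                for u in s.get("usages") or []
            ],
        )
        for s in doc.get("services") or []
    ]
    segments = []
    for g in doc.get("segments") or []:
        sched = None
        if g.get("schedule") is not None:
            sd = g["schedule"]
            sched = SegmentSchedule(
                phases=[
                    SchedulePhase(service=p["service"], years=p.get("years"))
                    for p in sd.get("phases") or []
                ],
                expected_total_duration=sd.get("expected_total_duration"),
            )
        segments.append(
            DemandSegment(
                id=g["id"],
                name=g.get("name", ""),
                schedule=sched,
                outcomes=dict(g.get("outcomes") or {}),
                behavior=dict(g.get("behavior") or {}),
            )
        )
    tdoc = doc.get("transitions") or {}
    transitions = TransitionModel(
        absorbing=list(tdoc.get("absorbing") or ["exit"]),
        rows={k: dict(v) for k, v in (tdoc.get("rows") or {}).items()},
        assumed_rows=list(tdoc.get("assumed_rows") or []),
    )
    region = None
    if doc.get("region") is not None:
        rd = doc["region"]
        region = RegionDemand(
            population=rd["population"],
            annual_incidence=rd["annual_incidence"],
            observed_segment_counts=dict(rd.get("observed_segment_counts") or {}),
        )
    return ModelDefinition(
        metadata=metadata,
        resources=resources,
        elements=elements,
        services=services,
        segments=segments,
        transitions=transitions,
        region=region,
    )


def model_to_dict(m: ModelDefinition) -> dict[str, Any]:
    """Inverse of :func:`model_from_dict` (external conventions: unit costs
    in currency units, utilization in percent)."""
    meta: dict[str, Any] = {}
    if m.metadata.name:
        meta["name"] = m.metadata.name
    meta["currency"] = m.metadata.currency
    if m.metadata.year is not None:
        meta["year"] = m.metadata.year
    if m.metadata.entry_segment is not None:
        meta["entry_segment"] = m.metadata.entry_segment
    if m.metadata.outcome_scales:
        meta["outcome_scales"] = {
            k: [v[0], v[1]] for k, v in m.metadata.outcome_scales.items()
        }
    if m.metadata.notes:
        meta["notes"] = m.metadata.notes

    doc: dict[str, Any] = {"metadata": meta}
    doc["resources"] = [
        {
            "id": r.id,
            "name": r.name,
            "kind": r.kind,
            "cost_basis": r.cost_basis,
            **({} if r.uncosted else {"unit_cost": _eur(r.unit_cost_cents)}),
        }
        for r in m.resources
    ]
    doc["elements"] = [
        {
            "id": e.id,
            "name": e.name,
            "requires": [
                {"resource": q.resource, "quantity": q.quantity}
                for q in e.requirements
            ],
        }
        for e in m.elements
    ]
    doc["services"] = [
        {
            "id": s.id,
            "name": s.name,
            "usages": [
                {
                    "element": u.element,
                    "frequency": u.frequency,
                    "utilization": u.utilization * 100,
                }
                for u in s.usages
            ],
        }
        for s in m.services
    ]
    doc["segments"] = []
    for g in m.segments:
        gd: dict[str, Any] = {"id": g.id, "name": g.name}
        if g.schedule is not None:
            gd["schedule"] = {
                "phases": [
                    {"service": p.service, **({} if p.years is None else {"years": p.years})}
                    for p in g.schedule.phases
                ],
                **(
                    {}
                    if g.schedule.expected_total_duration is None
                    else {"expected_total_duration": g.schedule.expected_total_duration}
                ),
            }
        if g.outcomes:
            gd["outcomes"] = dict(g.outcomes)
        if g.behavior:
            gd["behavior"] = dict(g.behavior)
        doc["segments"].append(gd)
    doc["transitions"] = {
        "absorbing": list(m.transitions.absorbing),
        "rows": {k: dict(v) for k, v in m.transitions.rows.items()},
    }
    if m.transitions.assumed_rows:
        doc["transitions"]["assumed_rows"] = list(m.transitions.assumed_rows)
    if m.region is not None:
        doc["region"] = {
            "population": m.region.population,
            "annual_incidence": m.region.annual_incidence,
        }
        if m.region.observed_segment_counts:
            doc["region"]["observed_segment_counts"] = dict(
                m.region.observed_segment_counts
            )
    return doc


def load_model(path: os.PathLike | str) -> ModelDefinition:
    """Load and validate a model definition from a YAML file.

    Raises :class:`ModelFormatError` on parse failure (with line context
    where the parser provides it) and :class:`ModelValidationError`
    carrying the findings when the parsed model violates invariants.
    """
    with open(path, "r", encoding="utf-8") as fh:
        try:
            doc = yaml.safe_load(fh)
        except yaml.YAMLError as exc:
            mark = getattr(exc, "problem_mark", None)
            where = f" at line {mark.line + 1}" if mark is not None else ""
            raise ModelFormatError(f"cannot parse {path}{where}: {exc}") from exc
    try:
        model = model_from_dict(doc)
    except ModelFormatError:
        raise
    except Exception as exc:  # pydantic / key errors -> findings, not a crash
        from .schema import Finding

        raise ModelValidationError(
            [Finding("schema", str(path), str(exc))]
        ) from exc
    findings = validate_model(model)
    if findings:
        raise ModelValidationError(findings)
    return model


def save_model(model: ModelDefinition, path: os.PathLike | str) -> None:
    """Write a model definition to YAML; ``load_model(save_model(m)) == m``
    field-for-field."""
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(
            model_to_dict(model), fh, sort_keys=False, allow_unicode=True, width=100
        )
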