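"""Microsimulation of individual patient journeys and service use.

Individual patients advance annually through the tenure-expanded chain by
sampling transition rows; per patient-year, each service element of the
occupied state's service is delivered as an all-or-nothing Bernoulli draw
with the element's utilization rate (all ``frequency`` deliveries or
none), so the expected delivered count is frequency x utilization — the
same expectation the deterministic costing engine uses, which makes the
simulation the stochastic oracle for every closed-form result.

Also hosts the programmatic builder of the bundled Dutch Type 2 Diabetes
case-study model (:func:`build_t2d_fixture`) and a random-model generator
for property tests.

All randomness flows through a single ``numpy.random.Generator`` seeded
explicitly; fixed seeds make every output bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources as _ilres
from typing import Optional

import numpy as np
import pandas as pd

from .cohort import ExpandedChain, expand_tenure
from .schema import (
    DemandSegment,
    Metadata,
    ModelDefinition,
    RegionDemand,
    Resource,
    ResourceRequirement,
    SchedulePhase,
    SegmentSchedule,
    Service,
    ServiceElement,
    ServiceElementUsage,
    TransitionModel,
)

__all__ = [
    "Trajectory",
    "SimulatedUse",
    "simulate_trajectories",
    "simulate_service_use",
    "estimate_transition_matrix",
    "build_t2d_fixture",
    "t2d_fixture_path",
    "random_model",
    "sample_outcomes",
]


@dataclass
class Trajectory:
    """One simulated patient: the expanded-state label occupied in each
    consecutive year from entry, and the absorbing state reached (``None``
    if the horizon truncated the journey)."""

    patient: int
    entry_year: int
    states: list[str]
    terminal: Optional[str]

    def __len__(self) -> int:
        return len(self.states)


@dataclass
class SimulatedUse:
    """Realized service use in one patient-year: delivered count per
    element, the realized cost (cents, uncosted resources contributing
    zero with ``partial`` set) and realized professional minutes."""

    patient: int
    year: int
    state: str
    counts: dict[str, int] = field(default_factory=dict)
    cost_cents: float = 0.0
    professional_minutes: float = 0.0
    partial: bool = False


def simulate_trajectories(
    model: ModelDefinition,
    n: int,
    horizon: int,
    seed: int,
    *,
    entry_segment: Optional[str] = None,
    chain: Optional[ExpandedChain] = None,
) -> list[Trajectory]:
    """Simulate ``n`` patients entering at ``entry_segment`` (default: the
    model's entry segment), each advancing annually by sampling the
    tenure-expanded transition row, until absorption or ``horizon``."""
    if n < 0:
        raise ValueError("n must be >= 0")
    chain = chain if chain is not None else expand_tenure(model)
    entry = entry_segment or model.entry_segment
    rng = np.random.default_rng(seed)
    nt = chain.n_transient
    cum = np.cumsum(chain.matrix, axis=1)
    labels = chain.labels
    paths: list[list[int]] = [[] for _ in range(n)]
    terminal: list[Optional[str]] = [None] * n
    state = np.full(n, chain.entry_index(entry), dtype=np.int64)
    alive = np.arange(n)
    for _ in range(horizon):
        if alive.size == 0:
            break
        for idx, st in zip(alive, state):
            paths[idx].append(st)
        u = rng.random(alive.size)
        nxt = np.empty(alive.size, dtype=np.int64)
        for s in np.unique(state):
            mask = state == s
            nxt[mask] = np.searchsorted(cum[s], u[mask], side="right")
        absorbed = nxt >= nt
        for idx, col in zip(alive[absorbed], nxt[absorbed]):
            terminal[idx] = chain.absorbing[col - nt]
        alive = alive[~absorbed]
        state = nxt[~absorbed]
    return [
        Trajectory(
            patient=i,
            entry_year=0,
            states=[labels[s] for s in paths[i]],
            terminal=terminal[i],
        )
        for i in range(n)
    ]


def simulate_service_use(
    model: ModelDefinition,
    trajectories: list[Trajectory],
    seed: int,
    *,
    per_delivery: bool = False,
    chain: Optional[ExpandedChain] = None,
) -> list[SimulatedUse]:
    """Realize service use for every patient-year of the trajectories.

    Default behaviour draws one Bernoulli(utilization) per element per
    patient-year (all ``frequency`` deliveries or none); with
    ``per_delivery`` each of the ``frequency`` deliveries is an
    independent Bernoulli(utilization) draw — identical expectation,
    smaller variance.  Realized cost prices the realized quantities at the
    resource unit costs with no expectation-rounding.
    """
    chain = chain if chain is not None else expand_tenure(model)
    rng = np.random.default_rng(seed)
    # per-service pricing tables
    svc_elements: dict[str, list] = {}
    for svc in model.services:
        rowset = []
        for usage in svc.usages:
            element = model.element(usage.element)
            cents_per_delivery = 0.0
            minutes_per_delivery = 0.0
            partial = False
            for req in element.requirements:
                res = model.resource(req.resource)
                if res.uncosted:
                    partial = True
                else:
                    cents_per_delivery += req.quantity * res.unit_cost_cents
                if res.cost_basis == "per_minute" and res.kind == "human":
                    minutes_per_delivery += req.quantity
            rowset.append(
                (usage, cents_per_delivery, minutes_per_delivery, partial)
            )
        svc_elements[svc.id] = rowset
    out: list[SimulatedUse] = []
    for traj in trajectories:
        for year, label in enumerate(traj.states):
            svc = chain.state(label).service
            use = SimulatedUse(patient=traj.patient, year=year + 1, state=label)
            for usage, cents, minutes, partial in svc_elements.get(svc, []):
                freq = int(round(usage.frequency))
                if per_delivery:
                    count = int(rng.binomial(freq, usage.utilization))
                else:
                    count = freq if rng.random() < usage.utilization else 0
                if count:
                    use.counts[usage.element] = count
                    use.cost_cents += count * cents
                    use.professional_minutes += count * minutes
                if partial:
                    use.partial = True
            out.append(use)
    return out


def realized_journey_costs(
    model: ModelDefinition,
    trajectories: list[Trajectory],
    seed: int,
    *,
    segment: Optional[str] = None,
    chain: Optional[ExpandedChain] = None,
) -> np.ndarray:
    """Per-patient realized journey cost (cents), vectorized over all
    patient-years: one Bernoulli(utilization) draw per element per
    patient-year, costed without expectation-rounding.  ``segment``
    restricts the total to patient-years spent in that segment.  Uncosted
    resources contribute zero (the deterministic engine flags the same
    years partial)."""
    chain = chain if chain is not None else expand_tenure(model)
    rng = np.random.default_rng(seed)
    n = len(trajectories)
    patient_of: list[int] = []
    service_of: list[str] = []
    for i, traj in enumerate(trajectories):
        for label in traj.states:
            xs = chain.state(label)
            if segment is not None and xs.segment != segment:
                continue
            patient_of.append(i)
            service_of.append(xs.service)
    patient_of_arr = np.asarray(patient_of, dtype=np.int64)
    service_of_arr = np.asarray(service_of)
    totals = np.zeros(n)
    for svc in model.services:
        mask = service_of_arr == svc.id
        if not mask.any():
            continue
        utils, amounts = [], []
        for usage in svc.usages:
            element = model.element(usage.element)
            cents = sum(
                req.quantity * model.resource(req.resource).unit_cost_cents
                for req in element.requirements
                if not model.resource(req.resource).uncosted
            )
            utils.append(usage.utilization)
            amounts.append(usage.frequency * cents)
        if not utils:
            continue
        draws = rng.random((int(mask.sum()), len(utils))) < np.asarray(utils)
        costs = draws @ np.asarray(amounts)
        np.add.at(totals, patient_of_arr[mask], costs)
    return totals


def estimate_transition_matrix(
    trajectories: list[Trajectory],
    *,
    absorbing: Optional[list[str]] = None,
) -> TransitionModel:
    """Maximum-likelihood segment-level transition rows from observed
    annual transitions: each probability is the observed frequency of the
    movement among all years at risk in the segment (tenure phases
    marginalized back to segments; stay probabilities implied)."""
    if not trajectories:
        raise ValueError("no trajectories")
    at_risk: dict[str, int] = {}
    moves: dict[str, dict[str, int]] = {}
    terminals: set[str] = set()
    for traj in trajectories:
        segs = [label.split(":")[0] for label in traj.states]
        steps = list(zip(segs, segs[1:]))
        if traj.terminal is not None and segs:
            steps.append((segs[-1], traj.terminal))
            terminals.add(traj.terminal)
        for a, b in steps:
            at_risk[a] = at_risk.get(a, 0) + 1
            if b != a:
                moves.setdefault(a, {})[b] = moves.setdefault(a, {}).get(b, 0) + 1
    rows = {
        seg: {tgt: cnt / at_risk[seg] for tgt, cnt in moves.get(seg, {}).items()}
        for seg in at_risk
    }
    observed_abs = sorted(terminals | {t for r in rows.values() for t in r if t not in at_risk})
    return TransitionModel(
        absorbing=list(absorbing) if absorbing is not None else observed_abs,
        rows=rows,
    )


def sample_outcomes(
    model: ModelDefinition,
    segment: str,
    outcome: str,
    n: int,
    seed: int,
) -> np.ndarray:
    """Synthetic individual outcome values for one segment: normal around
    the segment's declared mean with an assumed dispersion of 10% of the
    declared scale range, truncated to the scale.  The dispersion is an
    assumption (no individual-level data exists in the model); the draws
    exist to exercise reporting paths, not to emulate real variability."""
    seg = model.segment(segment)
    if outcome not in seg.outcomes:
        raise KeyError(f"segment {segment!r} has no outcome {outcome!r}")
    lo, hi = model.metadata.outcome_scales.get(outcome, (0.0, 100.0))
    rng = np.random.default_rng(seed)
    draws = rng.normal(seg.outcomes[outcome], 0.1 * (hi - lo), size=n)
    return np.clip(draws, lo, hi)


# ----------------------------------------------------------------------
# Bundled Type 2 Diabetes case-study model
# ----------------------------------------------------------------------

def t2d_fixture_path() -> str:
    """Path of the bundled T2D model definition file."""
    return str(_ilres.files("carejourney.fixtures") / "t2d_nwn_dwo.yaml")


def build_t2d_fixture() -> ModelDefinition:
    """The bundled Dutch T2D primary-care network model.

    Encodes the case-study services S1-S7, service elements SE1-SE20 with
    their per-delivery resource requirements, annual frequencies and
    utilization rates, the published per-minute tariffs, the demand
    segments DS1-DS5 with their tenure schedules, the annual transition
    probabilities between segments, the 2009 region demand, and the
    per-segment outcome/behaviour profiles.

    Unit costs for medication, insulin, test kits and some professionals
    are not published; those resources are deliberately uncosted and any
    aggregate touching them carries the partial-cost flag.  The DS3 and
    DS4 transition rows are placeholders consistent with the published
    mean durations (9 and 10 years, total leave 1/9 and 1/10) and are
    flagged ``assumed_rows``.
    """
    resources = [
        Resource(id="gp", name="GP", kind="human", unit_cost_cents=110),
        Resource(id="doctor_assistant", name="Doctor assistant", kind="human"),
        Resource(id="lab", name="Laboratory", kind="facility", unit_cost_cents=42),
        Resource(id="gp_nurse", name="GP&Nurse", kind="human", unit_cost_cents=71),
        Resource(id="dietician", name="Dietician", kind="human", unit_cost_cents=53),
        Resource(id="optometrist", name="Optometrist", kind="human", unit_cost_cents=110),
        Resource(id="practice_nurse", name="Practice nurse", kind="human", unit_cost_cents=29),
        Resource(id="diabetic_nurse", name="Diabetic nurse", kind="human", unit_cost_cents=58),
        Resource(id="lifestyle_consultant", name="Life style consultant", kind="human", unit_cost_cents=58),
        Resource(id="district_nurse", name="District nurse", kind="human"),
        Resource(id="pharmacist", name="Pharmacist", kind="human"),
        Resource(id="specialist", name="Specialist", kind="human"),
        Resource(id="test_kit", name="Glucose test kit", kind="consumable", cost_basis="per_item"),
        Resource(id="oral_medication", name="Oral medication", kind="consumable", cost_basis="per_item"),
        Resource(id="insulin", name="Insulin", kind="consumable", cost_basis="per_item"),
    ]

    def _el(eid, name, *reqs):
        return ServiceElement(
            id=eid,
            name=name,
            requirements=[ResourceRequirement(resource=r, quantity=q) for r, q in reqs],
        )

    elements = [
        _el("SE1", "Screening-visit", ("gp", 20)),
        _el("SE2", "Lab test in GP office", ("doctor_assistant", 5)),
        _el("SE3", "Lab-test-sampling", ("lab", 5)),
        _el("SE4", "Lab-test-analysis", ("lab", 1)),
        _el("SE5", "First visit", ("gp", 20)),
        _el("SE6", "Visit for diagnosis and care plan", ("gp", 20)),
        _el("SE7", "Follow-up visit", ("gp_nurse", 20)),
        _el("SE8", "Diet consultation", ("dietician", 45)),
        _el("SE9", "Eye care", ("optometrist", 5)),
        _el("SE10", "Foot care", ("practice_nurse", 5)),
        _el("SE11", "Self-test glucose monitoring", ("test_kit", 1)),
        _el("SE12", "Oral medication", ("oral_medication", 1)),
        _el("SE13", "Insulin medication", ("insulin", 1)),
        _el("SE14", "Education", ("diabetic_nurse", 20)),
        _el("SE15", "Specialized care", ("specialist", 10)),
        _el("SE16", "Life style program", ("lifestyle_consultant", 20)),
        _el("SE17", "Insulin injection by professional", ("district_nurse", 5), ("insulin", 1)),
        _el("SE18", "Delivering medication by professional", ("pharmacist", 5)),
        _el("SE19", "Prescription medicine", ("gp", 5)),
        _el("SE20", "Education for using insulin", ("diabetic_nurse", 20)),
    ]

    def _svc(sid, name, *usages):
        return Service(
            id=sid,
            name=name,
            usages=[
                ServiceElementUsage(element=e, frequency=f, utilization=u)
                for e, f, u in usages
            ],
        )

    services = [
        _svc("S1", "Screening", ("SE1", 1, 1.0), ("SE2", 0, 0.0)),
        _svc(
            "S2", "Diagnosis",
            ("SE3", 1, 1.0), ("SE4", 1, 1.0), ("SE5", 1, 1.0),
            ("SE6", 3, 1.0), ("SE14", 4, 1.0), ("SE16", 12, 1.0),
        ),
        _svc(
            "S3", "Chronic treatment with lifestyle advice",
            ("SE3", 1, 1.0), ("SE4", 1, 1.0), ("SE7", 4, 0.80),
            ("SE8", 1, 0.10), ("SE9", 1, 0.40), ("SE10", 1, 0.10),
        ),
        _svc(
            "S4", "Chronic treatment with lifestyle advice and oral medication",
            ("SE3", 1, 1.0), ("SE4", 1, 1.0), ("SE7", 4, 0.80),
            ("SE8", 1, 0.01), ("SE9", 1, 0.40), ("SE10", 1, 0.65),
            ("SE12", 365, 1.0), ("SE18", 4, 1.0), ("SE19", 4, 0.20),
        ),
        _svc(
            "S5", "Insulin therapy, first year with stabilization",
            ("SE3", 1, 1.0), ("SE4", 1, 1.0), ("SE7", 4, 1.0),
            ("SE8", 1, 0.01), ("SE9", 1, 0.40), ("SE10", 1, 0.65),
            ("SE11", 100, 1.0), ("SE12", 365, 0.90), ("SE13", 365, 1.0),
            ("SE17", 365, 0.02), ("SE18", 4, 1.0), ("SE20", 8, 1.0),
        ),
        _svc(
            "S6", "Insulin therapy, after first year",
            ("SE3", 1, 1.0), ("SE4", 1, 1.0), ("SE7", 4, 1.0),
            ("SE8", 1, 0.01), ("SE9", 1, 0.40), ("SE10", 1, 0.65),
            ("SE11", 100, 1.0), ("SE12", 365, 0.90), ("SE13", 365, 1.0),
            ("SE17", 365, 0.02), ("SE18", 4, 1.0),
        ),
        _svc("S7", "Specialized hospital care", ("SE15", 0, 0.0)),
    ]

    segments = [
        DemandSegment(
            id="DS1",
            name="High risk of developing diabetes (screening)",
            schedule=SegmentSchedule(
                phases=[SchedulePhase(service="S1")], expected_total_duration=1
            ),
        ),
        DemandSegment(
            id="DS2",
            name="T2D treated with lifestyle advice",
            schedule=SegmentSchedule(
                phases=[
                    SchedulePhase(service="S2", years=1),
                    SchedulePhase(service="S3"),
                ],
                expected_total_duration=3,
            ),
            outcomes={
                "satisfaction_services": 5.9,
                "own_health": 77.1,
                "satisfaction_own_health": 4.9,
                "pct_aware_hba1c": 42.4,
                "pct_hba1c_in_control": 84.0,
            },
            behavior={"pct_smokers": 7.0, "pct_drinkers": 72.0},
        ),
        DemandSegment(
            id="DS3",
            name="T2D treated with lifestyle advice and oral medication",
            schedule=SegmentSchedule(
                phases=[SchedulePhase(service="S4")], expected_total_duration=9
            ),
            outcomes={
                "satisfaction_services": 6.3,
                "own_health": 77.8,
                "satisfaction_own_health": 5.0,
                "pct_aware_hba1c": 56.1,
                "pct_hba1c_in_control": 87.0,
            },
            behavior={"pct_smokers": 11.4, "pct_drinkers": 66.8},
        ),
        DemandSegment(
            id="DS4",
            name="T2D treated with insulin injections",
            schedule=SegmentSchedule(
                phases=[
                    SchedulePhase(service="S5", years=1),
                    SchedulePhase(service="S6"),
                ],
                expected_total_duration=10,
            ),
            outcomes={
                "satisfaction_services": 6.1,
                "own_health": 69.1,
                "satisfaction_own_health": 4.1,
                "pct_aware_hba1c": 77.1,
                "pct_hba1c_in_control": 78.0,
            },
            behavior={"pct_smokers": 10.9, "pct_drinkers": 57.7},
        ),
        DemandSegment(
            id="DS5",
            name="Complicated T2D under specialist care",
            schedule=SegmentSchedule(
                phases=[SchedulePhase(service="S7")], expected_total_duration=1
            ),
        ),
    ]

    transitions = TransitionModel(
        absorbing=["DS5", "exit"],
        rows={
            "DS2": {"DS3": 0.313, "DS5": 0.05, "exit": 0.012},
            # placeholders: total leave = 1/9 and 1/10 (published mean
            # durations of 9 and 10 years); the split is assumed
            "DS3": {"DS4": 1 / 9 - 0.02, "DS5": 0.015, "exit": 0.005},
            "DS4": {"DS5": 0.08, "exit": 0.02},
        },
        assumed_rows=["DS3", "DS4"],
    )

    region = RegionDemand(
        population=443281,
        annual_incidence=910,
        observed_segment_counts={"DS2": 2687, "DS3": 8084, "DS4": 1451},
    )

    metadata = Metadata(
        name="T2D primary-care network, NWN&DWO region (NL)",
        currency="EUR",
        year=2009,
        entry_segment="DS2",
        outcome_scales={
            "satisfaction_services": (1, 7),
            "own_health": (0, 100),
            "satisfaction_own_health": (1, 7),
            "pct_aware_hba1c": (0, 100),
            "pct_hba1c_in_control": (0, 100),
        },
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


# ----------------------------------------------------------------------
# Random models for property tests
# ----------------------------------------------------------------------

def random_model(seed: int, *, max_segments: int = 6) -> ModelDefinition:
    """A random valid model for property tests: 2-6 single- or two-phase
    segments, total leave probabilities in [0.05, 0.95], 1-5 elements per
    service, per-minute unit costs in [0.10, 2.00] currency units."""
    rng = np.random.default_rng(seed)
    n_seg = int(rng.integers(2, max_segments + 1))
    resources, elements, services, segments = [], [], [], []
    rows: dict[str, dict[str, float]] = {}
    seg_ids = [f"G{i+1}" for i in range(n_seg)]
    eid = 0
    for i, gid in enumerate(seg_ids):
        two_phase = bool(rng.random() < 0.4)
        svc_ids = []
        for ph in range(2 if two_phase else 1):
            sid = f"V{gid}{ph+1}"
            n_el = int(rng.integers(1, 6))
            usages = []
            for _ in range(n_el):
                eid += 1
                rid = f"r{eid}"
                resources.append(
                    Resource(
                        id=rid,
                        kind="human",
                        unit_cost_cents=int(rng.integers(10, 201)),
                    )
                )
                elements.append(
                    ServiceElement(
                        id=f"e{eid}",
                        requirements=[
                            ResourceRequirement(
                                resource=rid,
                                quantity=float(rng.integers(1, 61)),
                            )
                        ],
                    )
                )
                usages.append(
                    ServiceElementUsage(
                        element=f"e{eid}",
                        frequency=float(rng.integers(1, 13)),
                        # whole-percent grid so the file format is lossless
                        utilization=float(rng.integers(5, 101)) / 100,
                    )
                )
            services.append(Service(id=sid, usages=usages))
            svc_ids.append(sid)
        total = int(rng.integers(3, 9))
        phases = (
            [SchedulePhase(service=svc_ids[0], years=1), SchedulePhase(service=svc_ids[1])]
            if two_phase
            else [SchedulePhase(service=svc_ids[0])]
        )
        segments.append(
            DemandSegment(
                id=gid,
                schedule=SegmentSchedule(phases=phases, expected_total_duration=total),
                outcomes={"score": float(rng.uniform(0, 100))},
            )
        )
        leave = float(rng.uniform(0.05, 0.95))
        row: dict[str, float] = {}
        onward = seg_ids[i + 1 :]
        if onward and rng.random() < 0.8:
            nxt = onward[int(rng.integers(len(onward)))]
            split = float(rng.uniform(0.2, 0.8))
            row[nxt] = leave * split
            row["exit"] = leave * (1 - split)
        else:
            row["exit"] = leave
        rows[gid] = row
    return ModelDefinition(
        metadata=Metadata(
            name=f"random model seed={seed}",
            entry_segment=seg_ids[0],
            outcome_scales={"score": (0, 100)},
        ),
        resources=resources,
        elements=elements,
        services=services,
        segments=segments,
        transitions=TransitionModel(absorbing=["exit"], rows=rows),
    )
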