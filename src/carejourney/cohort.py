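"""Discrete-time Markov cohort engine over demand segments.

The annual transition matrix acts on *tenure-expanded* states: a segment
whose schedule has several phases (e.g. a first diagnosis year followed by
open-ended chronic treatment) is split into one state per tenure year up
to the open phase, which self-loops.  Staying in the segment advances the
tenure clock; the probabilities of leaving are the same in every phase, so
marginalizing the phases recovers the original segment-level matrix row
for row.

Entrants join at the start of a year, consume the year's services, and
transition at year end.  With sub-stochastic transient rows, sojourns are
geometric: the mean time in a segment is the reciprocal of its total
annual leaving probability, and all expected-journey quantities follow
from the fundamental matrix ``N = (I - T)^-1`` of the absorbing chain.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .schema import ModelDefinition, TransitionModel

__all__ = [
    "ExpandedState",
    "ExpandedChain",
    "OccupancyTrajectory",
    "ImmortalStateError",
    "mean_sojourn",
    "expand_tenure",
    "cohort_project",
    "steady_state_occupancy",
    "expected_visits",
]


class ImmortalStateError(ValueError):
    """A state (or set of states) from which absorption is unreachable."""


@dataclass(frozen=True)
class ExpandedState:
    """A (segment, tenure phase) pair; ``phase`` is the 1-based tenure year
    index, the final (open-ended) phase collecting all later years."""

    segment: str
    phase: int
    service: str
    open_ended: bool

    @property
    def label(self) -> str:
        return f"{self.segment}:{self.phase}"


class ExpandedChain:
    """The tenure-expanded annual chain.

    ``matrix`` has one row per transient expanded state and one column per
    expanded state plus absorbing state, in that order; rows sum to 1.
    """

    def __init__(
        self,
        states: list[ExpandedState],
        absorbing: list[str],
        matrix: np.ndarray,
    ):
        self.states = states
        self.absorbing = list(absorbing)
        self.matrix = matrix
        self._index = {s.label: i for i, s in enumerate(states)}
        self._entry = {}
        for i, s in enumerate(states):
            self._entry.setdefault(s.segment, i)

    @property
    def n_transient(self) -> int:
        return len(self.states)

    @property
    def labels(self) -> list[str]:
        return [s.label for s in self.states]

    def state(self, label: str) -> ExpandedState:
        return self.states[self._index[label]]

    def index(self, label: str) -> int:
        return self._index[label]

    def entry_index(self, segment: str) -> int:
        """Index of the first tenure state of a segment."""
        return self._entry[segment]

    @property
    def transient_matrix(self) -> np.ndarray:
        """The transient-to-transient block ``T``."""
        return self.matrix[:, : self.n_transient]

    def marginal_rows(self) -> dict[str, dict[str, float]]:
        """Collapse tenure phases: the leave probabilities per segment.
        Within-segment tenure advances count as staying and are dropped,
        so the result is comparable to ``TransitionModel.rows``."""
        rows: dict[str, dict[str, float]] = {}
        targets = self.labels + self.absorbing
        for i, s in enumerate(self.states):
            row = rows.setdefault(s.segment, {})
            for j, p in enumerate(self.matrix[i]):
                if p <= 0:
                    continue
                tgt = targets[j]
                tgt_segment = (
                    self.states[j].segment if j < self.n_transient else tgt
                )
                if tgt_segment == s.segment:
                    continue  # implied stay
                row[tgt_segment] = row.get(tgt_segment, 0.0) + float(p)
        # leave probabilities are phase-invariant by construction; rows were
        # accumulated once per phase, so average them out
        counts = {s.segment: 0 for s in self.states}
        for s in self.states:
            counts[s.segment] += 1
        return {
            seg: {t: p / counts[seg] for t, p in row.items()}
            for seg, row in rows.items()
        }


def mean_sojourn(t: TransitionModel, segment: str) -> float:
    """Mean sojourn time in a segment, in years: the reciprocal of the sum
    of its annual leaving probabilities (geometric sojourn)."""
    if segment not in t.rows:
        raise KeyError(f"no transition row for segment {segment!r}")
    leave = t.leave_sum(segment)
    if leave <= 0:
        raise ImmortalStateError(f"segment {segment!r} has zero leaving probability")
    return 1.0 / leave


def expand_tenure(model: ModelDefinition) -> ExpandedChain:
    """Expand each scheduled segment of the transition model into
    tenure-year states; leaving probabilities are identical across phases
    and survival advances the phase (the final open phase self-loops)."""
    t = model.transitions
    states: list[ExpandedState] = []
    for sid in t.rows:
        seg = model.segment(sid)
        if seg.schedule is None or not seg.schedule.phases:
            states.append(ExpandedState(sid, 1, "", True))
            continue
        phases = seg.schedule.phases
        year = 1
        for i, p in enumerate(phases):
            last = i == len(phases) - 1
            if p.years is None:
                states.append(ExpandedState(sid, year, p.service, True))
            else:
                for k in range(p.years):
                    # the final tenure year of a fully closed schedule
                    # self-loops, acting as the open phase
                    open_here = last and k == p.years - 1
                    states.append(ExpandedState(sid, year, p.service, open_here))
                    year += 1
    absorbing = list(t.absorbing)
    n = len(states)
    matrix = np.zeros((n, n + len(absorbing)))
    labels = [s.label for s in states]
    entry = {}
    for i, s in enumerate(states):
        entry.setdefault(s.segment, i)
    abs_col = {a: n + k for k, a in enumerate(absorbing)}
    for i, s in enumerate(states):
        row = t.rows[s.segment]
        stay = 1.0 - sum(row.values())
        for target, p in row.items():
            if p <= 0:
                continue
            if target in abs_col:
                matrix[i, abs_col[target]] += p
            else:
                matrix[i, entry[target]] += p
        if stay > 0:
            seg_states = [j for j, x in enumerate(states) if x.segment == s.segment]
            pos = seg_states.index(i)
            nxt = i if (pos == len(seg_states) - 1) else seg_states[pos + 1]
            matrix[i, nxt] += stay
    return ExpandedChain(states, absorbing, matrix)


@dataclass
class OccupancyTrajectory:
    """Year-by-year expected patient counts per expanded state.

    ``occupancy[t - 1]`` is the population present *during* year ``t``
    (after that year's entrants joined, before year-end transitions);
    ``cumulative_exits[t - 1]`` counts absorptions through the end of year
    ``t``.  Conservation: occupancy during year t plus absorptions through
    year t-1 equals total inflow through year t.
    """

    chain: ExpandedChain
    occupancy: np.ndarray  # (horizon, n_transient)
    cumulative_exits: np.ndarray  # (horizon, n_absorbing)
    inflow_per_year: float

    @property
    def horizon(self) -> int:
        return self.occupancy.shape[0]

    def by_segment(self, year: int) -> dict[str, float]:
        """Occupancy during ``year`` (1-based) summed over tenure phases."""
        out: dict[str, float] = {}
        for i, s in enumerate(self.chain.states):
            out[s.segment] = out.get(s.segment, 0.0) + float(self.occupancy[year - 1, i])
        return out

    def conservation_gap(self) -> float:
        """Max relative violation of inflow = occupancy + absorptions."""
        worst = 0.0
        for t in range(1, self.horizon + 1):
            inflow = t * self.inflow_per_year
            held = self.occupancy[t - 1].sum()
            gone = self.cumulative_exits[t - 2].sum() if t >= 2 else 0.0
            worst = max(worst, abs(inflow - held - gone) / max(inflow, 1.0))
        return worst

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for t in range(1, self.horizon + 1):
            for i, s in enumerate(self.chain.states):
                rows.append(
                    {
                        "year": t,
                        "state": s.label,
                        "segment": s.segment,
                        "tenure_phase": s.phase,
                        "count": float(self.occupancy[t - 1, i]),
                    }
                )
            for k, a in enumerate(self.chain.absorbing):
                rows.append(
                    {
                        "year": t,
                        "state": a,
                        "segment": a,
                        "tenure_phase": 0,
                        "count": float(self.cumulative_exits[t - 1, k]),
                    }
                )
        return pd.DataFrame(rows)


def _entry_vector(chain: ExpandedChain, incidence: Mapping[str, float]) -> np.ndarray:
    e = np.zeros(chain.n_transient)
    for seg, n in incidence.items():
        if n < 0:
            raise ValueError("incidence must be >= 0")
        try:
            e[chain.entry_index(seg)] += n
        except KeyError:
            raise KeyError(f"entry segment {seg!r} not in transition model") from None
    return e


def cohort_project(
    model: ModelDefinition,
    incidence: Mapping[str, float],
    horizon: int,
    *,
    chain: Optional[ExpandedChain] = None,
) -> OccupancyTrajectory:
    """Project expected patient counts over ``horizon`` years under a
    constant annual incidence per entry segment: entrants join at year
    start, the transition matrix is applied at year end."""
    if horizon < 1:
        raise ValueError("horizon must be >= 1")
    chain = chain if chain is not None else expand_tenure(model)
    e = _entry_vector(chain, incidence)
    n, na = chain.n_transient, len(chain.absorbing)
    occupancy = np.zeros((horizon, n))
    exits = np.zeros((horizon, na))
    x = np.zeros(n)
    gone = np.zeros(na)
    T = chain.transient_matrix
    A = chain.matrix[:, n:]
    for t in range(horizon):
        x = x + e
        occupancy[t] = x
        gone = gone + x @ A
        exits[t] = gone
        x = x @ T
    return OccupancyTrajectory(chain, occupancy, exits, float(e.sum()))


def _fundamental_matrix(chain: ExpandedChain) -> np.ndarray:
    T = chain.transient_matrix
    n = chain.n_transient
    try:
        N = np.linalg.solve(np.eye(n) - T, np.eye(n))
    except np.linalg.LinAlgError as exc:
        raise ImmortalStateError(
            "transition model has a state set with no path to absorption"
        ) from exc
    if not np.all(np.isfinite(N)):
        raise ImmortalStateError("fundamental matrix is not finite")
    return N


def steady_state_occupancy(
    model: ModelDefinition,
    incidence: Mapping[str, float],
    *,
    chain: Optional[ExpandedChain] = None,
) -> dict[str, float]:
    """Long-run expected patient count per expanded state under constant
    annual incidence: the solution of the balance equations
    ``x = e + x T``, i.e. ``e N`` with ``N`` the fundamental matrix.
    Equals the limit of :func:`cohort_project`."""
    chain = chain if chain is not None else expand_tenure(model)
    e = _entry_vector(chain, incidence)
    x = e @ _fundamental_matrix(chain)
    return {s.label: float(x[i]) for i, s in enumerate(chain.states)}


def expected_visits(
    model: ModelDefinition,
    entry_segment: str,
    *,
    chain: Optional[ExpandedChain] = None,
) -> dict[str, float]:
    """Expected total years one entrant spends in each expanded state,
    from the absorbing-chain fundamental matrix (no simulation)."""
    chain = chain if chain is not None else expand_tenure(model)
    N = _fundamental_matrix(chain)
    try:
        i0 = chain.entry_index(entry_segment)
    except KeyError:
        raise KeyError(f"entry segment {entry_segment!r} not in transition model") from None
    return {s.label: float(N[i0, j]) for j, s in enumerate(chain.states)}


def expected_years_by_segment(
    model: ModelDefinition,
    entry_segment: str,
    *,
    chain: Optional[ExpandedChain] = None,
) -> dict[str, float]:
    """Expected years per segment (tenure phases summed) for one entrant."""
    chain = chain if chain is not None else expand_tenure(model)
    visits = expected_visits(model, entry_segment, chain=chain)
    out: dict[str, float] = {}
    for label, v in visits.items():
        seg = chain.state(label).segment
        out[seg] = out.get(seg, 0.0) + v
    return out
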