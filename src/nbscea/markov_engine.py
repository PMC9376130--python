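"""Deterministic Markov cohort engine.

Runs the per-disease, per-arm cohort trace over the disease's state set
(alive-no-sequela, one state per sequela, dead), with the trapezoid
half-cycle correction and discounting of both cost and QALY accruals.

Conventions
-----------
* Competing risks within a cycle are composed sequentially: death first
  (disease-specific and background mortality combined as independent
  hazards), then sequela onset among survivors. This guarantees row sums
  of 1 without probability overflow.
* Time in a state over cycle ``k`` is the trapezoid
  ``(occupancy[k] + occupancy[k+1]) / 2`` — the standard life-table
  half-cycle correction.
* Discounting is applied at mid-cycle (``(1+r)^-(k+0.5)``), consistent
  with the trapezoid accrual; end-of-cycle discounting is available as a
  switch for sensitivity work.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .parameters import CourseCurve

MASS_TOL = 1e-9

DEAD = "Dead"


@dataclass(frozen=True)
class StateSet:
    """Ordered Markov states for one disease: NS first, then sequelae, Dead last."""

    states: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.states[-1] != DEAD:
            raise ValueError("Dead must be the last (absorbing) state")

    def __len__(self) -> int:
        return len(self.states)

    def index(self, state: str) -> int:
        return self.states.index(state)

    @property
    def alive(self) -> tuple[str, ...]:
        return self.states[:-1]


def state_set_for(sequelae: Sequence[str]) -> StateSet:
    return StateSet(("NS", *sequelae, DEAD))


#: State set of a healthy (non-diseased) newborn: alive or dead.
HEALTHY_STATES = StateSet(("Alive", DEAD))


def combine_mortality(p_disease: float, p_background: float) -> float:
    """Combine disease-specific and other-cause annual death probabilities
    as independent competing hazards."""
    return 1.0 - (1.0 - p_disease) * (1.0 - p_background)


def build_transition_matrix(
    states: StateSet,
    p_death_disease: float,
    p_onset: Mapping[str, float],
    p_background: float,
) -> np.ndarray:
    """One-cycle transition matrix for a single age.

    From NS: die with the combined disease+background probability; among
    survivors, move to each sequela with its onset probability; the
    remainder stays in NS. From a sequela state: die with the same
    combined probability, otherwise stay (states are mutually exclusive,
    with no inter-sequela transitions). Dead is absorbing.
    """
    n = len(states)
    p_die = combine_mortality(p_death_disease, p_background)
    onset = {s: float(p_onset.get(s, 0.0)) for s in states.states[1:-1]}
    total_onset = sum(onset.values())
    if not 0.0 <= p_die <= 1.0 or total_onset > 1.0 + 1e-12 or any(v < 0 for v in onset.values()):
        raise ValueError(
            f"invalid one-cycle probabilities: p_die={p_die}, onsets={onset}"
        )
    m = np.zeros((n, n))
    ns, dead = 0, n - 1
    m[ns, dead] = p_die
    for seq, p in onset.items():
        m[ns, states.index(seq)] = (1.0 - p_die) * p
    m[ns, ns] = (1.0 - p_die) * (1.0 - total_onset)
    for seq in states.states[1:-1]:
        i = states.index(seq)
        m[i, dead] = p_die
        m[i, i] = 1.0 - p_die
    m[dead, dead] = 1.0
    return m


def build_matrices(
    states: StateSet,
    curve: CourseCurve | None,
    background: np.ndarray,
    horizon: int,
) -> np.ndarray:
    """Stack of age-indexed transition matrices, shape (horizon, n, n).

    ``curve=None`` means no disease-specific risks (a healthy cohort):
    only background mortality applies.
    """
    if curve is not None and curve.horizon < horizon:
        raise ValueError(f"course curve has {curve.horizon} entries, need {horizon}")
    if len(background) < horizon:
        raise ValueError(f"background mortality has {len(background)} entries, need {horizon}")
    out = np.empty((horizon, len(states), len(states)))
    for age in range(horizon):
        p_death = float(curve.p_death[age]) if curve is not None else 0.0
        p_onset = (
            {s: float(arr[age]) for s, arr in curve.p_onset.items()} if curve is not None else {}
        )
        out[age] = build_transition_matrix(states, p_death, p_onset, float(background[age]))
    return out


@dataclass
class CohortTrace:
    """Cycle-by-state occupancy of one cohort.

    ``occupancy`` has ``horizon + 1`` rows; row 0 is the starting
    distribution and row k+1 results from applying the age-k matrix.
    """

    states: StateSet
    occupancy: np.ndarray
    start_mass: float

    @property
    def horizon(self) -> int:
        return self.occupancy.shape[0] - 1

    def state_column(self, state: str) -> np.ndarray:
        return self.occupancy[:, self.states.index(state)]


def run_cohort_trace(
    matrices: np.ndarray,
    start: np.ndarray | float,
    states: StateSet,
) -> CohortTrace:
    """Propagate a starting occupancy through the age-indexed matrices.

    ``start`` may be a full occupancy vector or a scalar mass placed in the
    first (NS/Alive) state. Mass conservation is enforced at every cycle to
    within ``MASS_TOL`` of the starting mass.
    """
    horizon = matrices.shape[0]
    n = len(states)
    if np.isscalar(start):
        vec = np.zeros(n)
        vec[0] = float(start)
    else:
        vec = np.asarray(start, dtype=float).copy()
    if vec.min() < 0:
        raise ValueError("starting occupancy must be nonnegative")
    mass = float(vec.sum())
    rows = np.abs(matrices.sum(axis=2) - 1.0)
    if rows.max() > 1e-12:
        raise ValueError(f"non-stochastic transition matrix (max row-sum error {rows.max():.2e})")
    occ = np.empty((horizon + 1, n))
    occ[0] = vec
    for k in range(horizon):
        occ[k + 1] = occ[k] @ matrices[k]
        if abs(occ[k + 1].sum() - mass) > MASS_TOL * max(mass, 1.0):
            raise ValueError(f"cohort mass not conserved at cycle {k + 1}")
    return CohortTrace(states=states, occupancy=occ, start_mass=mass)


def per_cycle_state_time(trace: CohortTrace) -> np.ndarray:
    """Half-cycle-corrected person-time per cycle and state, shape (horizon, n)."""
    occ = trace.occupancy
    return 0.5 * (occ[:-1] + occ[1:])


def half_cycle_corrected_time(trace: CohortTrace) -> np.ndarray:
    """Total half-cycle-corrected person-time per state (person-years)."""
    return per_cycle_state_time(trace).sum(axis=0)


def discount_factor(rate: float, cycle: int | np.ndarray, timing: str = "mid") -> np.ndarray | float:
    """Discount multiplier for accruals over the given cycle.

    Mid-cycle timing uses exponent ``cycle + 0.5``; end-of-cycle uses
    ``cycle + 1``.
    """
    if rate < 0:
        raise ValueError("discount rate must be >= 0")
    offset = {"mid": 0.5, "end": 1.0}.get(timing)
    if offset is None:
        raise ValueError(f"unknown discount timing {timing!r}")
    return (1.0 + rate) ** -(np.asarray(cycle, dtype=float) + offset)


def discount_factors(rate: float, horizon: int, timing: str = "mid") -> np.ndarray:
    return np.asarray(discount_factor(rate, np.arange(horizon), timing=timing))


@dataclass
class OutcomeTotals:
    """Discounted cost and QALY totals, with the per-cycle accrual streams."""

    cost: float
    qaly: float
    cost_per_cycle: np.ndarray
    qaly_per_cycle: np.ndarray


def accumulate_outcomes(
    trace: CohortTrace,
    state_costs: np.ndarray,
    state_utilities: np.ndarray,
    rate: float,
    timing: str = "mid",
) -> OutcomeTotals:
    """Accrue discounted cost and QALYs over the trace.

    ``state_costs`` may be a per-state vector (n,) or an age-dependent
    matrix (horizon, n); ``state_utilities`` is a per-state vector. Both
    are multiplied by half-cycle-corrected state-time and discounted per
    cycle.
    """
    time = per_cycle_state_time(trace)  # (H, n)
    horizon, n = time.shape
    costs = np.asarray(state_costs, dtype=float)
    if costs.ndim == 1:
        costs = np.broadcast_to(costs, (horizon, n))
    elif costs.shape != (horizon, n):
        raise ValueError(f"state_costs shape {costs.shape} incompatible with trace ({horizon}, {n})")
    utils = np.asarray(state_utilities, dtype=float)
    if utils.shape != (n,):
        raise ValueError(f"need one utility per state, got shape {utils.shape}")
    df = discount_factors(rate, horizon, timing=timing)
    cost_stream = (time * costs).sum(axis=1) * df
    qaly_stream = (time * utils).sum(axis=1) * df
    return OutcomeTotals(
        cost=float(cost_stream.sum()),
        qaly=float(qaly_stream.sum()),
        cost_per_cycle=cost_stream,
        qaly_per_cycle=qaly_stream,
    )


def trace_frame(
    trace: CohortTrace,
    outcomes: OutcomeTotals | None = None,
) -> pd.DataFrame:
    """Tabular export: one row per (cycle, state) with occupancy, plus the
    per-cycle discounted accrual streams when provided."""
    horizon = trace.horizon
    records = []
    for k in range(horizon + 1):
        for i, s in enumerate(trace.states.states):
            records.append({
                "cycle": k,
                "state": s,
                "occupancy": trace.occupancy[k, i],
                "cost_accrued": (outcomes.cost_per_cycle[k - 1] if outcomes is not None and k > 0 and i == 0 else np.nan),
                "qaly_accrued": (outcomes.qaly_per_cycle[k - 1] if outcomes is not None and k > 0 and i == 0 else np.nan),
            })
    return pd.DataFrame.from_records(records)
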