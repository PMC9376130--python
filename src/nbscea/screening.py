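"""Decision-tree screening stage and per-arm lifetime evaluation.

Applies assay performance to the birth cohort (expected-value arithmetic,
not integer sampling), prices the screening stage, and turns each
disease/arm into the age-by-state annual cost streams the Markov engine
accrues.

Cost conventions
----------------
* Screening-stage costs (assay fee, confirmation of positives, program
  overheads) are charged undiscounted at year 0; transport and lost
  productivity are *not* counted at this stage because sampling happens
  in the maternity hospital.
* A false positive incurs one confirmation test, then exits the model
  (the confirmatory test is treated as perfect).
* Detected (screened-arm) patients accrue treatment, follow-up visits,
  transport and family lost productivity annually for life; sequela
  states add the sequela-care cost.
* Undetected (unscreened-arm) patients accrue costs only once
  symptomatic, which by default means on entry into a sequela state
  (configurable to a fixed onset age); they never accrue the screening
  program's follow-up visits.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from . import markov_engine as me
from .course_synthesis import BackgroundMortality, default_background_mortality
from .parameters import DiseaseSpec, ParameterSet

ARMS = ("screened", "unscreened")

#: Cost component names, in reporting order.
COST_COMPONENTS = (
    "screening", "confirmation", "program", "treatment",
    "sequela_care", "followup", "transport", "productivity",
)


@dataclass(frozen=True)
class StrategySpec:
    """A screening strategy: which diseases are screened, by which assay."""

    name: str
    assays: Mapping[str, str] = field(default_factory=dict)  # code -> "IF" | "MSMS"

    @property
    def screened_diseases(self) -> tuple[str, ...]:
        return tuple(sorted(self.assays))

    def assay_for(self, code: str) -> str | None:
        return self.assays.get(code)

    @property
    def panel_assay(self) -> str | None:
        """The assay that draws the sample: MS/MS if any disease uses it
        (one blood sample covers the whole panel), else IF, else none."""
        if not self.assays:
            return None
        return "MSMS" if "MSMS" in self.assays.values() else "IF"


def current_screening() -> StrategySpec:
    """The status-quo comparator: PKU screened by immunofluorescence only."""
    return StrategySpec(name="current", assays={"PKU": "IF"})


def expanded_screening(ps: ParameterSet, codes: tuple[str, ...] | None = None,
                       name: str | None = None) -> StrategySpec:
    """An MS/MS strategy covering ``codes`` (default: the whole panel)."""
    codes = tuple(codes) if codes is not None else tuple(ps.disease_codes)
    return StrategySpec(name=name or f"msms_{len(codes)}", assays={c: "MSMS" for c in codes})


def no_screening() -> StrategySpec:
    return StrategySpec(name="none", assays={})


@dataclass
class ClassificationCounts:
    """Expected screening-test outcome masses over one birth cohort."""

    true_positives: dict[str, float]
    false_negatives: dict[str, float]
    false_positives: float
    true_negatives: float

    @property
    def total(self) -> float:
        return (sum(self.true_positives.values()) + sum(self.false_negatives.values())
                + self.false_positives + self.true_negatives)


def classify_cohort(strategy: StrategySpec, ps: ParameterSet,
                    cohort_size: float | None = None) -> ClassificationCounts:
    """Expected TP/FN per screened disease and FP/TN over the non-diseased rest.

    Only individuals with a *screened* disease can be true positives; the
    false-positive mass comes from everyone else failing the panel assay's
    specificity.
    """
    cohort = float(cohort_size if cohort_size is not None else ps.econ.cohort_size)
    tp: dict[str, float] = {}
    fn: dict[str, float] = {}
    screened_inc = 0.0
    for code in strategy.screened_diseases:
        d = ps.disease(code)
        assay = ps.assays[strategy.assay_for(code)]
        cases = d.incidence * cohort
        tp[code] = cases * assay.sensitivity
        fn[code] = cases * (1.0 - assay.sensitivity)
        screened_inc += d.incidence
    rest = (1.0 - screened_inc) * cohort
    if strategy.panel_assay is None:
        fp = 0.0
    else:
        fp = rest * (1.0 - ps.assays[strategy.panel_assay].specificity)
    return ClassificationCounts(true_positives=tp, false_negatives=fn,
                                false_positives=fp, true_negatives=rest - fp)


def screening_stage_cost_per_newborn(strategy: StrategySpec, ps: ParameterSet) -> dict[str, float]:
    """Undiscounted year-0 screening-stage cost components per newborn.

    Returns a dict with ``screening`` (one panel sample), ``confirmation``
    (expected confirmation tests for true and false positives) and
    ``program`` (fixed program costs spread over the cohort plus
    per-person overheads). Empty strategies cost nothing.
    """
    out = {"screening": 0.0, "confirmation": 0.0, "program": 0.0}
    if strategy.panel_assay is None:
        return out
    counts = classify_cohort(strategy, ps, cohort_size=1.0)
    out["screening"] = ps.assays[strategy.panel_assay].screen_cost
    for code, mass in counts.true_positives.items():
        out["confirmation"] += mass * ps.assays[strategy.assay_for(code)].confirm_cost
    out["confirmation"] += counts.false_positives * ps.assays[strategy.panel_assay].confirm_cost
    out["program"] = ps.costs.program_cost_per_newborn(ps.econ.cohort_size)
    return out


def _onset_age(ps: ParameterSet) -> int | None:
    """Fixed symptomatic-onset age for unscreened cost accrual, or None for
    the default sequela-entry rule."""
    setting = ps.econ.unscreened_cost_onset
    if setting == "sequela":
        return None
    return int(setting)


def lifetime_cost_components(
    disease: DiseaseSpec, arm: str, ps: ParameterSet, assay: str | None = None
) -> dict[str, np.ndarray]:
    """Annual cost matrices (horizon x states) per component for one arm.

    States are ordered NS, then the disease's sequelae, then Dead.
    ``assay`` names the screening technology whose follow-up schedule the
    detected patient is on (screened arm only).
    """
    if arm not in ARMS:
        raise ValueError(f"unknown arm {arm!r}")
    horizon = ps.econ.horizon
    states = me.state_set_for(disease.sequelae)
    n = len(states)
    zeros = lambda: np.zeros((horizon, n))
    comp = {name: zeros() for name in COST_COMPONENTS}
    treat_by_age = np.array([disease.treatment_cost_at(a) for a in range(horizon)])
    alive = list(range(n - 1))  # all but Dead
    seq_states = states.states[1:-1]

    if arm == "screened":
        followup = ps.assays[assay].followup_cost if assay is not None else 0.0
        for i in alive:
            comp["treatment"][:, i] = treat_by_age
            comp["followup"][:, i] = followup
            comp["transport"][:, i] = ps.costs.transport
            comp["productivity"][:, i] = ps.costs.lost_productivity
        for seq in seq_states:
            comp["sequela_care"][:, states.index(seq)] = ps.costs.sequela_care[seq]
    else:
        onset_age = _onset_age(ps)
        if onset_age is None:
            # untreated until symptoms: costs begin on entry into a sequela state
            for seq in seq_states:
                i = states.index(seq)
                comp["treatment"][:, i] = treat_by_age
                comp["sequela_care"][:, i] = ps.costs.sequela_care[seq]
                comp["transport"][:, i] = ps.costs.transport
                comp["productivity"][:, i] = ps.costs.lost_productivity
        else:
            for i in alive:
                comp["treatment"][onset_age:, i] = treat_by_age[onset_age:]
                comp["transport"][onset_age:, i] = ps.costs.transport
                comp["productivity"][onset_age:, i] = ps.costs.lost_productivity
            for seq in seq_states:
                i = states.index(seq)
                comp["sequela_care"][:, i] = ps.costs.sequela_care[seq]
    return comp


def state_utilities(disease: DiseaseSpec, ps: ParameterSet) -> np.ndarray:
    states = me.state_set_for(disease.sequelae)
    vals = [ps.utilities.values["NS"]]
    vals += [ps.utilities.values[s] for s in disease.sequelae]
    vals.append(ps.utilities.values["Dead"])
    return np.array(vals)


@dataclass
class ArmOutcome:
    """Discounted per-case outcome of one disease arm."""

    qaly: float
    cost: float
    cost_components: dict[str, float]


def evaluate_arm(
    disease: DiseaseSpec,
    arm: str,
    ps: ParameterSet,
    background: BackgroundMortality | None = None,
    assay: str | None = None,
    rate: float | None = None,
) -> ArmOutcome:
    """Trace one affected newborn through the Markov model for one arm.

    Returns discounted cost (by component) and QALYs per case. The course
    curve for the arm must be attached to the disease spec.
    """
    curve = disease.course_screened if arm == "screened" else disease.course_unscreened
    if curve is None:
        raise ValueError(f"{disease.code}: missing course curve for arm {arm!r}")
    if background is None:
        background = default_background_mortality(ps.econ.horizon)
    if rate is None:
        rate = ps.econ.discount_rate
    states = me.state_set_for(disease.sequelae)
    mats = me.build_matrices(states, curve, np.asarray(background), ps.econ.horizon)
    trace = me.run_cohort_trace(mats, 1.0, states)
    utils = state_utilities(disease, ps)
    comp = lifetime_cost_components(disease, arm, ps, assay=assay)
    timing = ps.econ.discount_timing
    totals: dict[str, float] = {}
    qaly = None
    for name, matrix in comp.items():
        res = me.accumulate_outcomes(trace, matrix, utils, rate, timing=timing)
        totals[name] = res.cost
        qaly = res.qaly  # identical across components
    cost = float(sum(totals.values()))
    return ArmOutcome(qaly=float(qaly), cost=cost, cost_components=totals)


def healthy_qaly(
    ps: ParameterSet,
    background: BackgroundMortality | None = None,
    rate: float | None = None,
) -> float:
    """Discounted QALYs of a healthy newborn (utility 1 while alive, zero cost)."""
    if background is None:
        background = default_background_mortality(ps.econ.horizon)
    if rate is None:
        rate = ps.econ.discount_rate
    mats = me.build_matrices(me.HEALTHY_STATES, None, np.asarray(background), ps.econ.horizon)
    trace = me.run_cohort_trace(mats, 1.0, me.HEALTHY_STATES)
    utils = np.array([ps.utilities.values["Alive"], ps.utilities.values["Dead"]])
    res = me.accumulate_outcomes(trace, np.zeros(2), utils, rate, timing=ps.econ.discount_timing)
    return res.qaly
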