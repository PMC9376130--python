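"""One-way sensitivity analyses: discount-rate sweep and tornado diagram.

The sweep re-runs the full base-case comparison (whole MS/MS panel vs
current screening) at each discount rate, re-discounting both costs and
effects. The tornado perturbs one parameter at a time to its low and
high value — incidences by ±50%, costs by ±10%, utilities to their
published bounds — and reports the resulting ICER interval, sorted by
its width. All perturbation runs operate on deep copies, so the input
parameter set is restored bit-identically.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from . import cea
from .course_synthesis import BackgroundMortality, default_background_mortality
from .parameters import ParameterSet, apply_override

#: Default discount-rate grid: 0% to 10% inclusive in 1% steps.
DEFAULT_RATES = tuple(round(0.01 * i, 2) for i in range(11))

INCIDENCE_SPREAD = 0.50
COST_SPREAD = 0.10


@dataclass(frozen=True)
class ParamPerturbation:
    """One tornado parameter: where it lives and its low/high values.

    ``mode`` is ``"absolute"`` (low/high replace the value at ``path``) or
    ``"scale"`` (low/high multiply every leaf under the group named by
    ``path`` — used for the age-banded treatment costs and the aggregate
    program cost, which move jointly).
    """

    path: str
    label: str
    low: float
    high: float
    rule: str
    mode: str = "absolute"


@dataclass(frozen=True)
class TornadoEntry:
    parameter: ParamPerturbation
    icer_low: float
    icer_high: float
    base_icer: float

    @property
    def range(self) -> float:
        return abs(self.icer_high - self.icer_low)


def sweep_discount_rate(
    ps: ParameterSet,
    rates: Sequence[float] | None = None,
    background: BackgroundMortality | None = None,
) -> list[tuple[float, float, bool]]:
    """ICER of the full panel vs current screening at each discount rate.

    Returns ``(rate, icer, below_threshold)`` triples. The entry at the
    baseline rate uses exactly the base-case code path.
    """
    if rates is None:
        rates = DEFAULT_RATES
    if background is None:
        background = default_background_mortality(ps.econ.horizon)
    out = []
    for rate in rates:
        if not 0.0 <= rate <= 1.0:
            raise ValueError(f"discount rate {rate} outside [0, 1]")
        comp = cea.base_case_comparison(ps, background, rate=rate)
        out.append((float(rate), comp.icer, bool(comp.below_threshold)))
    return out


def default_perturbations(ps: ParameterSet) -> list[ParamPerturbation]:
    """The standard one-way parameter grid.

    One entry per disease incidence (±50%), per cost parameter (±10%;
    treatment costs move both age bands jointly, the program cost moves
    all its pieces jointly), and per health-state utility (published
    bounds).
    """
    out: list[ParamPerturbation] = []
    for d in ps.diseases:
        out.append(ParamPerturbation(
            path=f"diseases.{d.code}.incidence", label=f"P_{d.code}",
            low=d.incidence * (1 - INCIDENCE_SPREAD), high=d.incidence * (1 + INCIDENCE_SPREAD),
            rule=f"incidence ±{INCIDENCE_SPREAD:.0%}"))
    lo, hi = 1 - COST_SPREAD, 1 + COST_SPREAD
    cost_rule = f"cost ±{COST_SPREAD:.0%}"
    for d in ps.diseases:
        out.append(ParamPerturbation(
            path=f"diseases.{d.code}.treatment", label=f"CT_{d.code}",
            low=lo, high=hi, rule=cost_rule, mode="scale"))
    for assay, tag in (("MSMS", "MS"), ("IF", "FA")):
        a = ps.assays[assay]
        out.append(ParamPerturbation(path=f"assays.{assay}.screen_cost", label=f"C_{tag}Scr",
                                     low=a.screen_cost * lo, high=a.screen_cost * hi, rule=cost_rule))
        out.append(ParamPerturbation(path=f"assays.{assay}.confirm_cost", label=f"C_{tag}Com",
                                     low=a.confirm_cost * lo, high=a.confirm_cost * hi, rule=cost_rule))
        out.append(ParamPerturbation(path=f"assays.{assay}.followup_cost", label=f"CVisit{tag}",
                                     low=a.followup_cost * lo, high=a.followup_cost * hi, rule=cost_rule))
    for seq, value in ps.costs.sequela_care.items():
        out.append(ParamPerturbation(path=f"costs.sequela_care.{seq}", label=f"C{seq}",
                                     low=value * lo, high=value * hi, rule=cost_rule))
    out.append(ParamPerturbation(path="costs.transport", label="Ctraffic",
                                 low=ps.costs.transport * lo, high=ps.costs.transport * hi, rule=cost_rule))
    out.append(ParamPerturbation(path="costs.lost_productivity", label="CWage",
                                 low=ps.costs.lost_productivity * lo, high=ps.costs.lost_productivity * hi,
                                 rule=cost_rule))
    out.append(ParamPerturbation(path="costs.program", label="C_Pr",
                                 low=lo, high=hi, rule=cost_rule, mode="scale"))
    for state, (blo, bhi) in ps.utilities.bounds.items():
        out.append(ParamPerturbation(path=f"utilities.values.{state}", label=f"U_{state}",
                                     low=blo, high=bhi, rule="published bounds"))
    return out


def apply_perturbation(ps: ParameterSet, p: ParamPerturbation, side: str) -> None:
    """Set one parameter to its low or high value, in place."""
    value = {"low": p.low, "high": p.high}[side]
    if p.mode == "absolute":
        apply_override(ps, p.path, value)
        return
    # scale mode: multiply every leaf in the addressed group
    if p.path == "costs.program":
        ps.costs.program_fixed = {k: v * value for k, v in ps.costs.program_fixed.items()}
        ps.costs.program_per_person = {k: v * value for k, v in ps.costs.program_per_person.items()}
    elif p.path.startswith("diseases.") and p.path.endswith(".treatment"):
        d = ps.disease(p.path.split(".")[1])
        d.treatment_cost_0_5 *= value
        d.treatment_cost_6_82 *= value
    else:
        raise ValueError(f"unknown scale-mode path {p.path!r}")


def tornado(
    ps: ParameterSet,
    perturbations: Iterable[ParamPerturbation] | None = None,
    background: BackgroundMortality | None = None,
) -> list[TornadoEntry]:
    """One-way ICER intervals, widest first.

    Each parameter is set to its low then high value with everything else
    at base; sorting is stable, and equal ranges keep parameter-path
    alphabetical order.
    """
    if perturbations is None:
        perturbations = default_perturbations(ps)
    if background is None:
        background = default_background_mortality(ps.econ.horizon)
    base = cea.base_case_comparison(ps, background).icer
    entries: list[TornadoEntry] = []
    for p in perturbations:
        icers = {}
        for side in ("low", "high"):
            trial = ps.copy()
            apply_perturbation(trial, p, side)
            icers[side] = cea.base_case_comparison(trial, background).icer
        entries.append(TornadoEntry(parameter=p, icer_low=icers["low"],
                                    icer_high=icers["high"], base_icer=base))
    entries.sort(key=lambda e: (-e.range, e.parameter.path))
    return entries
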