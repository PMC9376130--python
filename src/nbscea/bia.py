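"""Budget impact analysis: the government's 10-year screening budget.

Projects, undiscounted (budget-holder convention), the yearly government
outlay of a screening program over 2019-2028:

* screening line: cohort x assay sample fee x the government's 80%
  screening share. Program overheads and family-borne shares are outside
  the budget lines.
* treatment line: cumulative over birth cohorts — each cohort's surviving
  patients accrue their annual treatment cost (disease treatment by age
  band plus sequela care; no follow-up visits, transport, or family
  productivity, which the treatment budget does not carry) times the
  government's 60% treatment share. Diseases whose untreated course kills
  within the first two years are excluded from the treatment line
  entirely; by default the exclusion set is derived from the course
  library (2-year cumulative unscreened mortality above 50%).

Screened diseases use the screened arm's occupancy and costs (detected
patients, mostly sequela-free); unscreened diseases use the unscreened
arm, whose costs only start at symptomatic onset.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import markov_engine as me
from . import screening as scr
from .cea import LadderResult
from .course_synthesis import BackgroundMortality, default_background_mortality
from .parameters import DiseaseSpec, ParameterSet

EARLY_DEATH_CUM_MORTALITY = 0.50  # 2-year unscreened threshold for exclusion

#: BIA treatment-line cost components (government-reimbursed care).
TREATMENT_COMPONENTS = ("treatment", "sequela_care")


def early_death_flags(ps: ParameterSet) -> dict[str, bool]:
    """Which diseases the treatment line excludes.

    An explicit ``early_death_flag`` on the disease wins; otherwise the
    flag is derived from the unscreened course curve: cumulative
    disease-specific mortality over the first two years above 50%.
    """
    out = {}
    for d in ps.diseases:
        if d.early_death_flag is not None:
            out[d.code] = bool(d.early_death_flag)
            continue
        if d.course_unscreened is None:
            out[d.code] = False
            continue
        p = d.course_unscreened.p_death[:2]
        cum = 1.0 - float(np.prod(1.0 - p))
        out[d.code] = cum > EARLY_DEATH_CUM_MORTALITY
    return out


def annual_treatment_cost_by_age(
    disease: DiseaseSpec,
    arm: str,
    ps: ParameterSet,
    background: BackgroundMortality,
    years: int,
) -> np.ndarray:
    """Expected annual treatment+sequela-care cost per affected newborn,
    by age 0..years-1 (undiscounted, half-cycle person-time)."""
    curve = disease.course_screened if arm == "screened" else disease.course_unscreened
    if curve is None:
        raise ValueError(f"{disease.code}: missing course curve for arm {arm!r}")
    states = me.state_set_for(disease.sequelae)
    mats = me.build_matrices(states, curve, np.asarray(background), ps.econ.horizon)
    trace = me.run_cohort_trace(mats, 1.0, states)
    time = me.per_cycle_state_time(trace)[:years]  # (years, n)
    comp = scr.lifetime_cost_components(disease, arm, ps)
    cost_matrix = sum(comp[name] for name in TREATMENT_COMPONENTS)[:years]
    return (time * cost_matrix).sum(axis=1)


@dataclass
class BIATable:
    """Year-by-year government budget of one program, in million RMB."""

    program: str
    years: list[int]
    screening: np.ndarray
    treatment: np.ndarray

    @property
    def total(self) -> np.ndarray:
        return self.screening + self.treatment

    @property
    def decade_screening(self) -> float:
        return float(self.screening.sum())

    @property
    def decade_treatment(self) -> float:
        return float(self.treatment.sum())

    @property
    def decade_total(self) -> float:
        return float(self.total.sum())


def project_budget(
    ps: ParameterSet,
    strategy: scr.StrategySpec,
    years: int | None = None,
    start_year: int = 2019,
    background: BackgroundMortality | None = None,
) -> BIATable:
    """Project one program's government budget over the horizon.

    Each year a fresh cohort of ``cohort_size`` newborns is screened; the
    treatment line in year t sums over all cohorts born so far, tracked at
    their actual ages.
    """
    if years is None:
        years = ps.econ.bia_years
    if years < 1:
        raise ValueError("years must be >= 1")
    if background is None:
        background = default_background_mortality(ps.econ.horizon)
    cohort = ps.econ.cohort_size
    sample_fee = (
        ps.assays[strategy.panel_assay].screen_cost if strategy.panel_assay is not None else 0.0
    )
    screening_per_year = cohort * sample_fee * ps.econ.gov_share_screening / 1e6

    flags = early_death_flags(ps)
    # per-age government treatment cost per newborn of one cohort (RMB)
    cost_by_age = np.zeros(years)
    for d in ps.diseases:
        if flags[d.code]:
            continue
        arm = "screened" if strategy.assay_for(d.code) is not None else "unscreened"
        per_case = annual_treatment_cost_by_age(d, arm, ps, background, years)
        cost_by_age += d.incidence * per_case
    cost_by_age *= cohort * ps.econ.gov_share_treatment

    treatment = np.array([cost_by_age[: t + 1].sum() for t in range(years)]) / 1e6
    return BIATable(
        program=strategy.name,
        years=[start_year + t for t in range(years)],
        screening=np.full(years, screening_per_year),
        treatment=treatment,
    )


def budget_difference(msms: BIATable, iff: BIATable) -> pd.DataFrame:
    """Per-year and decade difference rows between two programs.

    Mirrors the published layout: per-program screening/treatment/total
    columns in million RMB plus difference columns, with a final total row.
    """
    if msms.years != iff.years:
        raise ValueError("budget tables cover different years")
    frame = pd.DataFrame({
        "year": msms.years,
        "msms_screening": msms.screening,
        "msms_treatment": msms.treatment,
        "msms_total": msms.total,
        "if_screening": iff.screening,
        "if_treatment": iff.treatment,
        "if_total": iff.total,
    })
    frame["diff_screening"] = frame["msms_screening"] - frame["if_screening"]
    frame["diff_total"] = frame["msms_total"] - frame["if_total"]
    totals = frame.drop(columns="year").sum()
    totals["year"] = "total"
    return pd.concat([frame, totals.to_frame().T[frame.columns]], ignore_index=True)


def compare_ladder_budgets(
    ladder: LadderResult,
    ps: ParameterSet,
    background: BackgroundMortality | None = None,
) -> list[tuple[str, BIATable]]:
    """Decade budgets of every ladder strategy.

    The MS/MS sample fee is panel-independent, so all strategies share the
    same screening line; only the treatment line varies with the panel.
    """
    if background is None:
        background = default_background_mortality(ps.econ.horizon)
    return [
        (strat.name, project_budget(ps, strat, background=background))
        for strat, _ in ladder.steps
    ]
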