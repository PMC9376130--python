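"""Cost-effectiveness analysis: strategy evaluation, ICERs, rankings, ladder.

A strategy's discounted effectiveness (E) and cost (C) per newborn are
incidence-weighted mixtures over healthy newborns (background mortality,
utility 1), each screened disease's screened (detected-and-treated) arm,
and each unscreened disease's unscreened arm, plus the year-0 screening
stage. Pairwise comparisons report the incremental cost-effectiveness
ratio (ICER), judged against the threshold of three times per-capita GDP.

The single-disease ranking evaluates screening each non-PKU disease alone
(charging the full MS/MS sample cost — a single-disease program cannot
share its blood sample) against not screening it; the strategy ladder
then adds diseases to the PKU base in ascending ICER order and compares
each cumulative panel (one shared MS/MS sample) against the status quo.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import screening as scr
from .course_synthesis import BackgroundMortality, default_background_mortality
from .parameters import ParameterSet

#: Increments smaller than this count as "no effectiveness difference".
EFFECT_EPS = 1e-12


@dataclass
class CEResult:
    """Discounted per-newborn cost and effectiveness of one strategy."""

    strategy: str
    E: float  # QALYs per newborn
    C: float  # RMB per newborn
    components: dict[str, float] = field(default_factory=dict)

    @property
    def ce_ratio(self) -> float:
        return self.C / self.E


@dataclass
class IcerComparison:
    """Pairwise incremental comparison of two strategies."""

    intervention: CEResult
    comparator: CEResult
    threshold: float

    @property
    def incr_E(self) -> float:
        return self.intervention.E - self.comparator.E

    @property
    def incr_C(self) -> float:
        return self.intervention.C - self.comparator.C

    @property
    def defined(self) -> bool:
        return abs(self.incr_E) >= EFFECT_EPS

    @property
    def icer(self) -> float:
        return self.incr_C / self.incr_E if self.defined else math.inf

    @property
    def below_threshold(self) -> bool | None:
        if not self.defined:
            return None
        return self.icer <= self.threshold

    @property
    def dominant(self) -> bool:
        """Intervention costs less and yields more QALYs."""
        return self.defined and self.incr_E > 0 and self.incr_C < 0

    @property
    def dominated(self) -> bool:
        return self.defined and self.incr_E < 0 and self.incr_C > 0


def icer(intervention: CEResult, comparator: CEResult, threshold: float) -> IcerComparison:
    return IcerComparison(intervention=intervention, comparator=comparator, threshold=threshold)


def evaluate_strategy(
    strategy: scr.StrategySpec,
    ps: ParameterSet,
    background: BackgroundMortality | None = None,
    rate: float | None = None,
    diseases: tuple[str, ...] | None = None,
) -> CEResult:
    """Discounted per-newborn E and C of a strategy.

    ``diseases`` restricts the modelled disease population (used by the
    single-disease comparisons, where everyone without that one disease
    counts as healthy); the default models all diseases in the set.
    """
    if background is None:
        background = default_background_mortality(ps.econ.horizon)
    if rate is None:
        rate = ps.econ.discount_rate
    codes = tuple(diseases) if diseases is not None else tuple(ps.disease_codes)

    stage = scr.screening_stage_cost_per_newborn(strategy, ps)
    components: dict[str, float] = {name: 0.0 for name in scr.COST_COMPONENTS}
    for name, value in stage.items():
        components[name] += value

    total_inc = ps.total_incidence(codes)
    E = (1.0 - total_inc) * scr.healthy_qaly(ps, background, rate)
    for code in codes:
        d = ps.disease(code)
        assay = strategy.assay_for(code)
        arm = "screened" if assay is not None else "unscreened"
        out = scr.evaluate_arm(d, arm, ps, background, assay=assay, rate=rate)
        E += d.incidence * out.qaly
        for name, value in out.cost_components.items():
            components[name] += d.incidence * value
    C = float(sum(components.values()))
    return CEResult(strategy=strategy.name, E=float(E), C=C, components=components)


@dataclass
class LadderResult:
    """Single-disease ranking plus the cumulative strategy ladder."""

    ranking: list[tuple[str, IcerComparison]]
    steps: list[tuple[scr.StrategySpec, IcerComparison]]

    @property
    def ranked_codes(self) -> list[str]:
        return [code for code, _ in self.ranking]

    @property
    def icer_series(self) -> list[float]:
        return [comp.icer for _, comp in self.steps]


def rank_single_disease_programs(
    ps: ParameterSet,
    background: BackgroundMortality | None = None,
    rate: float | None = None,
) -> list[tuple[str, IcerComparison]]:
    """Rank the 11 non-PKU diseases by the ICER of screening each alone.

    For each disease, {MS/MS screening of that one disease} is compared
    with {no screening of it}, everything else held fixed. Sorted by ICER
    ascending; undefined ICERs (no effectiveness difference) rank last;
    ties break alphabetically by disease code.
    """
    if background is None:
        background = default_background_mortality(ps.econ.horizon)
    threshold = ps.econ.icer_threshold
    entries: list[tuple[str, IcerComparison]] = []
    for code in ps.disease_codes:
        if code == "PKU":
            continue
        single = scr.expanded_screening(ps, codes=(code,), name=f"msms_{code}")
        none = scr.no_screening()
        a = evaluate_strategy(single, ps, background, rate, diseases=(code,))
        b = evaluate_strategy(none, ps, background, rate, diseases=(code,))
        entries.append((code, icer(a, b, threshold)))
    entries.sort(key=lambda e: (e[1].icer if e[1].defined else math.inf, e[0]))
    return entries


def build_strategy_ladder(
    ranking: list[tuple[str, IcerComparison]],
    ps: ParameterSet,
    background: BackgroundMortality | None = None,
    rate: float | None = None,
) -> LadderResult:
    """The cumulative screening strategies implied by the ranking.

    Strategy k screens PKU plus the top-k ranked diseases by MS/MS and is
    compared against the status quo (PKU by IF, nothing else). The last
    strategy is the full nationally recommended panel.
    """
    if background is None:
        background = default_background_mortality(ps.econ.horizon)
    threshold = ps.econ.icer_threshold
    comparator = evaluate_strategy(scr.current_screening(), ps, background, rate)
    steps: list[tuple[scr.StrategySpec, IcerComparison]] = []
    ranked = [code for code, _ in ranking]
    for k in range(1, len(ranked) + 1):
        codes = ("PKU", *ranked[:k])
        strat = scr.expanded_screening(ps, codes=codes, name=f"strategy_{k}")
        res = evaluate_strategy(strat, ps, background, rate)
        steps.append((strat, icer(res, comparator, threshold)))
    return LadderResult(ranking=list(ranking), steps=steps)


def base_case_comparison(
    ps: ParameterSet,
    background: BackgroundMortality | None = None,
    rate: float | None = None,
) -> IcerComparison:
    """The headline comparison: the full MS/MS panel vs current screening."""
    if background is None:
        background = default_background_mortality(ps.econ.horizon)
    expanded = evaluate_strategy(scr.expanded_screening(ps, name="expanded"), ps, background, rate)
    current = evaluate_strategy(scr.current_screening(), ps, background, rate)
    return icer(expanded, current, ps.econ.icer_threshold)
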