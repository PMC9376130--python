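"""Result tables and run manifests.

Emits the analysis outputs as CSV files with explicit unit headers plus a
JSON summary, at the reporting precision of the source tables: E and C to
3 decimals (QALYs / RMB per newborn), ICERs rounded to integers
(RMB/QALY), budget lines to 2 decimals (million RMB). Raw unrounded
values are kept in memory; rounding happens only at emission.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import __version__
from .bia import BIATable, budget_difference
from .cea import CEResult, IcerComparison, LadderResult
from .parameters import ParameterSet
from .sensitivity import TornadoEntry


def ce_table(comparisons: Sequence[IcerComparison]) -> pd.DataFrame:
    """Strategy-level CE table: E, incr E, C, incr C, ICER, C/E.

    The first comparison's comparator is included as its own row.
    """
    rows = []
    if comparisons:
        base = comparisons[0].comparator
        rows.append({
            "strategy": base.strategy,
            "E_qaly_per_newborn": base.E,
            "incr_E_qaly": float("nan"),
            "C_rmb_per_newborn": base.C,
            "incr_C_rmb": float("nan"),
            "icer_rmb_per_qaly": float("nan"),
            "c_over_e_rmb_per_qaly": base.ce_ratio,
        })
    for comp in comparisons:
        rows.append({
            "strategy": comp.intervention.strategy,
            "E_qaly_per_newborn": comp.intervention.E,
            "incr_E_qaly": comp.incr_E,
            "C_rmb_per_newborn": comp.intervention.C,
            "incr_C_rmb": comp.incr_C,
            "icer_rmb_per_qaly": comp.icer if comp.defined else float("inf"),
            "c_over_e_rmb_per_qaly": comp.intervention.ce_ratio,
        })
    frame = pd.DataFrame(rows)
    for col in ("E_qaly_per_newborn", "incr_E_qaly"):
        frame[col] = frame[col].round(6)
    for col in ("C_rmb_per_newborn", "incr_C_rmb"):
        frame[col] = frame[col].round(3)
    frame["icer_rmb_per_qaly"] = frame["icer_rmb_per_qaly"].round(0)
    frame["c_over_e_rmb_per_qaly"] = frame["c_over_e_rmb_per_qaly"].round(3)
    return frame


def ranking_table(ranking: Sequence[tuple[str, IcerComparison]]) -> pd.DataFrame:
    """Single-disease programs sorted by ICER (ascending)."""
    rows = []
    for rank, (code, comp) in enumerate(ranking, start=1):
        rows.append({
            "disease": code,
            "rank": rank,
            "C_msms_rmb_per_newborn": round(comp.intervention.C, 3),
            "C_none_rmb_per_newborn": round(comp.comparator.C, 3),
            "incr_C_rmb": round(comp.incr_C, 3),
            "incr_E_qaly": round(comp.incr_E, 8),
            "icer_rmb_per_qaly": round(comp.icer) if comp.defined else float("inf"),
        })
    return pd.DataFrame(rows)


def ladder_table(ladder: LadderResult) -> pd.DataFrame:
    """The cumulative-strategy series behind the ladder figure."""
    rows = []
    for k, (strat, comp) in enumerate(ladder.steps, start=1):
        rows.append({
            "strategy_index": k,
            "diseases": "+".join(("PKU", *ladder.ranked_codes[:k])),
            "incr_E_qaly": round(comp.incr_E, 8),
            "incr_C_rmb": round(comp.incr_C, 3),
            "icer_rmb_per_qaly": round(comp.icer) if comp.defined else float("inf"),
            "below_threshold": comp.below_threshold,
        })
    return pd.DataFrame(rows)


def sweep_table(sweep: Sequence[tuple[float, float, bool]]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"discount_rate": r, "icer_rmb_per_qaly": round(i), "below_threshold": b}
         for r, i, b in sweep]
    )


def tornado_table(entries: Sequence[TornadoEntry]) -> pd.DataFrame:
    rows = []
    for rank, e in enumerate(entries, start=1):
        rows.append({
            "parameter": e.parameter.label,
            "path": e.parameter.path,
            "rule": e.parameter.rule,
            "icer_low_rmb_per_qaly": round(e.icer_low),
            "icer_high_rmb_per_qaly": round(e.icer_high),
            "range_rmb_per_qaly": round(e.range),
            "base_icer_rmb_per_qaly": round(e.base_icer),
            "rank": rank,
        })
    return pd.DataFrame(rows)


def bia_table(msms: BIATable, iff: BIATable) -> pd.DataFrame:
    """Year-by-year budget rows (million RMB, government share, undiscounted)."""
    frame = budget_difference(msms, iff)
    value_cols = [c for c in frame.columns if c != "year"]
    frame[value_cols] = frame[value_cols].astype(float).round(2)
    frame.columns = [c if c == "year" else f"{c}_million_rmb" for c in frame.columns]
    return frame


def ladder_budget_table(budgets: Sequence[tuple[str, BIATable]]) -> pd.DataFrame:
    rows = []
    for idx, (name, table) in enumerate(budgets, start=1):
        rows.append({
            "strategy_index": idx,
            "strategy": name,
            "decade_screening_million_rmb": round(table.decade_screening, 2),
            "decade_treatment_million_rmb": round(table.decade_treatment, 2),
            "decade_total_million_rmb": round(table.decade_total, 2),
        })
    return pd.DataFrame(rows)


def run_manifest(ps: ParameterSet, library_version: str) -> dict:
    return {
        "tool": "nbscea",
        "tool_version": __version__,
        "parameter_set": ps.name,
        "parameter_hash": ps.content_hash(),
        "course_library_version": library_version,
    }


def write_outputs(outdir: str | Path, tables: dict[str, pd.DataFrame],
                  summary: dict, manifest: dict) -> list[Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, frame in tables.items():
        path = outdir / f"{name}.csv"
        frame.to_csv(path, index=False)
        written.append(path)
    for name, doc in (("summary", summary), ("manifest", manifest)):
        path = outdir / f"{name}.json"
        path.write_text(json.dumps(doc, indent=2, sort_keys=True, default=float) + "\n")
        written.append(path)
    return written
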