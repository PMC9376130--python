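"""Synthetic disease-course curves and background mortality.

Published age-specific mortality and sequela-onset data for the 12 panel
IEMs are scarce; this module generates deterministic per-disease, per-arm
curves from compact templates so the whole pipeline is testable end to
end. The packaged template library is versioned and frozen: it was
calibrated once so that, run through the engine at the baseline settings,
it reproduces the qualitative structure reported for the Shenzhen
evaluation (single-disease ICER ranking, the ladder shape with only the
first strategy above the threshold, and the dominant tornado parameters).
It is *not* an estimate of real IEM natural history; a transcription of
real age-specific curves can be dropped in through the same tabular
format.

Templates are deliberately simple: an annual death probability for ages
0-1 (``early_mortality``) and for ages >= 2 (``late_mortality``), plus a
constant annual onset probability per sequela inside an onset window
(default ages 0-4). Screened (detected and treated early) arms must
dominate unscreened arms age by age — screening cannot worsen the course.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .markov_engine import (
    HEALTHY_STATES,
    accumulate_outcomes,
    build_matrices,
    half_cycle_corrected_time,
    run_cohort_trace,
)
from .parameters import CourseCurve, ParameterError, SEQUELAE, Violation

TEMPLATE_RESOURCE = "course_templates"


@dataclass(frozen=True)
class CourseTemplate:
    """Compact generator for one disease arm's course curve."""

    disease: str
    arm: str  # "screened" | "unscreened"
    early_mortality: float  # annual death probability, ages 0-1
    late_mortality: float  # annual death probability, ages >= 2
    sequela_onset: Mapping[str, float] = field(default_factory=dict)
    onset_window: tuple[int, int] = (0, 5)  # [start, end) ages

    def violations(self) -> list[Violation]:
        out = []
        prefix = f"templates.{self.disease}.{self.arm}"
        for attr in ("early_mortality", "late_mortality"):
            v = getattr(self, attr)
            if not 0.0 <= v <= 1.0:
                out.append(Violation(f"{prefix}.{attr}", "must lie in [0, 1]", v))
        for seq, v in self.sequela_onset.items():
            if not 0.0 <= v <= 1.0:
                out.append(Violation(f"{prefix}.sequela_onset.{seq}", "must lie in [0, 1]", v))
        if self.onset_window[0] < 0 or self.onset_window[1] < self.onset_window[0]:
            out.append(Violation(f"{prefix}.onset_window", "must be a nonnegative age range", self.onset_window))
        return out


def synthesize_curves(template: CourseTemplate, horizon: int) -> CourseCurve:
    """Expand a template into an age-indexed :class:`CourseCurve`.

    Deterministic: identical templates yield bit-identical curves.
    """
    if horizon < 1:
        raise ValueError("horizon must be >= 1")
    bad = template.violations()
    if bad:
        raise ParameterError(bad)
    p_death = np.full(horizon, float(template.late_mortality))
    p_death[: min(2, horizon)] = float(template.early_mortality)
    lo, hi = template.onset_window
    p_onset = {}
    for seq, rate in template.sequela_onset.items():
        arr = np.zeros(horizon)
        arr[lo: min(hi, horizon)] = float(rate)
        p_onset[seq] = arr
    curve = CourseCurve(p_death=p_death, p_onset=p_onset)
    bad = curve.violations(prefix=f"templates.{template.disease}.{template.arm}")
    if bad:
        raise ParameterError(bad)
    return curve


@dataclass(frozen=True)
class BackgroundMortality:
    """Age-indexed annual all-cause death probability of the general
    population, applied identically to both arms and to healthy newborns."""

    p_death: np.ndarray

    def __len__(self) -> int:
        return len(self.p_death)

    def __getitem__(self, i):
        return self.p_death[i]

    def __array__(self, dtype=None, copy=None):
        return np.asarray(self.p_death, dtype=dtype)


# Fitted once against the engine so that a healthy cohort traced over the
# 82-cycle horizon has an undiscounted (half-cycle-corrected) life
# expectancy of ~82 years, the anchor for Shenzhen residents in 2018:
# a flat child/adult rate up to age 60 and a Gompertz ramp beyond it.
_BG_CHILD_RATE = 5.0e-5
_BG_RAMP_AGE = 60
_BG_RAMP_RATE0 = 1.0e-4
_BG_RAMP_GROWTH = 0.20


def default_background_mortality(horizon: int = 82) -> BackgroundMortality:
    """Monotone non-decreasing background mortality curve for the cohort."""
    if horizon < 1:
        raise ValueError("horizon must be >= 1")
    ages = np.arange(horizon)
    q = np.where(
        ages < _BG_RAMP_AGE,
        _BG_CHILD_RATE,
        _BG_RAMP_RATE0 * np.exp(_BG_RAMP_GROWTH * (ages - _BG_RAMP_AGE)),
    )
    return BackgroundMortality(p_death=np.minimum(q, 1.0))


def healthy_life_expectancy(
    background: BackgroundMortality, horizon: int | None = None
) -> float:
    """Undiscounted half-cycle-corrected life expectancy of a healthy cohort,
    truncated at the model horizon."""
    if horizon is None:
        horizon = len(background)
    mats = build_matrices(HEALTHY_STATES, None, np.asarray(background), horizon)
    trace = run_cohort_trace(mats, 1.0, HEALTHY_STATES)
    return float(half_cycle_corrected_time(trace)[0])


# ---------------------------------------------------------------------------
# packaged template library


def _load_template_doc() -> dict:
    text = resources.files("nbscea.data").joinpath(f"{TEMPLATE_RESOURCE}.yaml").read_text()
    return yaml.safe_load(text)


def load_templates(source: str | Path | Mapping | None = None) -> dict[tuple[str, str], CourseTemplate]:
    """Load course templates from the packaged library or a user document."""
    if source is None:
        doc = _load_template_doc()
    elif isinstance(source, Mapping):
        doc = dict(source)
    else:
        doc = yaml.safe_load(Path(source).read_text())
    window = tuple(doc.get("onset_window", (0, 5)))
    out: dict[tuple[str, str], CourseTemplate] = {}
    for disease, arms in doc["templates"].items():
        for arm, t in arms.items():
            out[(disease, arm)] = CourseTemplate(
                disease=disease,
                arm=arm,
                early_mortality=float(t.get("early_mortality", 0.0)),
                late_mortality=float(t.get("late_mortality", 0.0)),
                sequela_onset={k: float(v) for k, v in t.get("onset", {}).items()},
                onset_window=tuple(t.get("onset_window", window)),
            )
    return out


def library_version() -> str:
    return str(_load_template_doc().get("version", "0"))


def baseline_course_library(horizon: int = 82) -> dict[tuple[str, str], CourseCurve]:
    """The packaged synthetic course library: 12 diseases x 2 arms.

    Screened-arm death and onset probabilities are verified to be <= the
    unscreened arm's age by age (the premise that early detection cannot
    worsen the course).
    """
    templates = load_templates()
    library = {key: synthesize_curves(t, horizon) for key, t in templates.items()}
    for (disease, arm) in list(library):
        if arm != "screened":
            continue
        s, u = library[(disease, "screened")], library[(disease, "unscreened")]
        if np.any(s.p_death > u.p_death + 1e-15):
            raise ParameterError([Violation(
                f"templates.{disease}", "screened death probability must not exceed unscreened", disease)])
        for seq, arr in s.p_onset.items():
            if np.any(arr > u.p_onset.get(seq, np.zeros(horizon)) + 1e-15):
                raise ParameterError([Violation(
                    f"templates.{disease}.onset.{seq}",
                    "screened onset probability must not exceed unscreened", disease)])
    return library


# ---------------------------------------------------------------------------
# tabular serialization (same shape a transcription of real age-specific
# curves would have, so measured data can replace the synthetic library)


def course_library_to_frame(library: Mapping[tuple[str, str], CourseCurve]) -> pd.DataFrame:
    rows = []
    for (disease, arm), curve in sorted(library.items()):
        for age in range(curve.horizon):
            row = {"disease": disease, "arm": arm, "age": age,
                   "p_death_disease": float(curve.p_death[age])}
            for seq in SEQUELAE:
                if seq in curve.p_onset:
                    row[f"p_onset_{seq}"] = float(curve.p_onset[seq][age])
            rows.append(row)
    return pd.DataFrame.from_records(rows)


def course_library_from_frame(frame: pd.DataFrame) -> dict[tuple[str, str], CourseCurve]:
    out: dict[tuple[str, str], CourseCurve] = {}
    for (disease, arm), grp in frame.groupby(["disease", "arm"]):
        grp = grp.sort_values("age")
        ages = grp["age"].to_numpy()
        if not np.array_equal(ages, np.arange(len(ages))):
            raise ParameterError([Violation(
                f"course_library.{disease}.{arm}.age", "ages must be contiguous from 0", list(ages[:5]))])
        p_onset = {}
        for seq in SEQUELAE:
            col = f"p_onset_{seq}"
            if col in grp.columns and grp[col].notna().any():
                p_onset[seq] = grp[col].fillna(0.0).to_numpy(dtype=float)
        out[(disease, arm)] = CourseCurve(
            p_death=grp["p_death_disease"].to_numpy(dtype=float), p_onset=p_onset)
    return out


def load_course_library(path: str | Path) -> dict[tuple[str, str], CourseCurve]:
    return course_library_from_frame(pd.read_csv(path))


def save_course_library(library: Mapping[tuple[str, str], CourseCurve], path: str | Path) -> None:
    course_library_to_frame(library).to_csv(path, index=False)
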