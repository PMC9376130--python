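"""Model parameter set: types, validation, loading/saving, and the packaged baseline.

The parameter set mirrors the inputs of the Shenzhen 2018 evaluation of
expanded newborn screening: assay performance (immunofluorescence vs tandem
mass spectrometry), per-disease incidences and treatment costs for the 12
inborn errors of metabolism (IEMs) of the national recommended panel,
sequela-care costs, health-state utilities, and the economic settings
(3% discount rate, 200,000-newborn cohort, 82 one-year cycles, an ICER
threshold of three times per-capita GDP).

All monetary values are 2018 RMB.
"""

from __future__ import annotations

import copy
import hashlib
import json
import re
from dataclasses import dataclass, field, fields
from importlib import resources
from pathlib import Path
from typing import Any, Iterable, Mapping, Sequence

import numpy as np
import yaml

#: The 12 IEMs of the nationally recommended MS/MS panel.
DISEASE_CODES = (
    "PKU", "MSUD", "CIT1", "CIT2", "HCY", "MMA",
    "IVA", "GA1", "PA", "PCD", "MCAD", "VLCAD",
)

#: Sequela (chronic-damage) states: development delay, neurological damage,
#: mental retardation, renal damage.
SEQUELAE = ("DD", "ND", "MR", "RD")

#: Canonical disease -> sequela mapping of the state-transition structure.
CANONICAL_SEQUELAE: dict[str, tuple[str, ...]] = {
    "CIT1": ("MR",),
    "CIT2": ("MR",),
    "HCY": ("MR",),
    "PKU": ("ND",),
    "GA1": ("ND",),
    "MCAD": ("DD",),
    "PCD": ("DD",),
    "VLCAD": ("DD",),
    "IVA": ("ND", "RD"),
    "MMA": ("ND", "RD"),
    "PA": ("ND", "RD"),
    "MSUD": ("ND", "DD"),
}

ASSAY_NAMES = ("IF", "MSMS")

#: Resource name of the packaged baseline parameter document.
BASELINE_RESOURCE = "shenzhen_2018"


class ParameterError(ValueError):
    """Raised when a parameter document fails validation.

    Carries the full list of :class:`Violation` records so that every
    offending path is reported at once.
    """

    def __init__(self, violations: Sequence["Violation"]):
        self.violations = list(violations)
        lines = [f"  {v.path}: {v.rule} (observed {v.value!r})" for v in self.violations]
        super().__init__("invalid parameter set:\n" + "\n".join(lines))


@dataclass(frozen=True)
class Violation:
    """One validation finding: the offending path, the rule, the observed value."""

    path: str
    rule: str
    value: Any


@dataclass(eq=False)
class CourseCurve:
    """Age-indexed annual disease-course probabilities for one disease arm.

    ``p_death`` is the annual probability of disease-specific death (excess
    over background mortality); ``p_onset`` maps each sequela in the
    disease's sequela set to an annual onset probability while alive and
    sequela-free.
    """

    p_death: np.ndarray
    p_onset: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        self.p_death = np.asarray(self.p_death, dtype=float)
        self.p_onset = {k: np.asarray(v, dtype=float) for k, v in self.p_onset.items()}

    @property
    def horizon(self) -> int:
        return int(self.p_death.shape[0])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CourseCurve):
            return NotImplemented
        return (
            np.array_equal(self.p_death, other.p_death)
            and set(self.p_onset) == set(other.p_onset)
            and all(np.array_equal(self.p_onset[k], other.p_onset[k]) for k in self.p_onset)
        )

    def violations(self, prefix: str = "course") -> list[Violation]:
        out: list[Violation] = []
        if np.any((self.p_death < 0) | (self.p_death > 1)):
            out.append(Violation(f"{prefix}.p_death", "entries must lie in [0, 1]",
                                 float(self.p_death.min() if self.p_death.min() < 0 else self.p_death.max())))
        total = self.p_death.astype(float).copy()
        for seq, arr in self.p_onset.items():
            if arr.shape != self.p_death.shape:
                out.append(Violation(f"{prefix}.p_onset.{seq}", "length must match p_death", arr.shape[0]))
                continue
            if np.any((arr < 0) | (arr > 1)):
                out.append(Violation(f"{prefix}.p_onset.{seq}", "entries must lie in [0, 1]",
                                     float(arr.min() if arr.min() < 0 else arr.max())))
            total = total + arr
        bad = np.nonzero(total > 1.0 + 1e-12)[0]
        if bad.size:
            age = int(bad[0])
            out.append(Violation(f"{prefix}[age={age}]",
                                 "per-age sum of competing transition probabilities must be <= 1",
                                 float(total[age])))
        return out

    def to_dict(self) -> dict:
        return {
            "p_death": [float(x) for x in self.p_death],
            "p_onset": {k: [float(x) for x in v] for k, v in self.p_onset.items()},
        }

    @classmethod
    def from_dict(cls, doc: Mapping) -> "CourseCurve":
        return cls(p_death=np.asarray(doc["p_death"], dtype=float),
                   p_onset={k: np.asarray(v, dtype=float) for k, v in doc.get("p_onset", {}).items()})


@dataclass
class AssaySpec:
    """One screening assay: test performance and its unit costs (RMB)."""

    name: str
    sensitivity: float
    specificity: float
    screen_cost: float
    confirm_cost: float
    followup_cost: float  # per person-year, 4 visits/year

    def violations(self, prefix: str) -> list[Violation]:
        out = []
        for attr in ("sensitivity", "specificity"):
            v = getattr(self, attr)
            if not 0.0 <= v <= 1.0:
                out.append(Violation(f"{prefix}.{attr}", "must lie in [0, 1]", v))
        for attr in ("screen_cost", "confirm_cost", "followup_cost"):
            v = getattr(self, attr)
            if v < 0:
                out.append(Violation(f"{prefix}.{attr}", "must be >= 0", v))
        return out


@dataclass
class DiseaseSpec:
    """One IEM: incidence, sequela set, age-banded treatment costs, course curves.

    Treatment costs are split at age 5 (``treatment_cost_0_5`` covers ages
    0-5, ``treatment_cost_6_82`` ages 6 and above). ``early_death_flag``
    marks diseases excluded from the budget-impact treatment line because
    untreated disease kills within the first two years; ``None`` means
    "derive from the unscreened course curve".
    """

    code: str
    incidence: float
    sequelae: tuple[str, ...]
    treatment_cost_0_5: float
    treatment_cost_6_82: float
    course_screened: CourseCurve | None = None
    course_unscreened: CourseCurve | None = None
    early_death_flag: bool | None = None
    incidence_assumed: bool = False

    def treatment_cost_at(self, age: int) -> float:
        return self.treatment_cost_0_5 if age <= 5 else self.treatment_cost_6_82

    def violations(self, prefix: str) -> list[Violation]:
        out = []
        if self.code not in DISEASE_CODES:
            out.append(Violation(f"{prefix}.code", "unknown disease code", self.code))
        if not 0.0 < self.incidence < 0.01:
            out.append(Violation(f"{prefix}.incidence", "must lie in (0, 0.01)", self.incidence))
        for attr in ("treatment_cost_0_5", "treatment_cost_6_82"):
            v = getattr(self, attr)
            if v < 0:
                out.append(Violation(f"{prefix}.{attr}", "must be >= 0", v))
        if self.code in CANONICAL_SEQUELAE and tuple(self.sequelae) != CANONICAL_SEQUELAE[self.code]:
            out.append(Violation(f"{prefix}.sequelae",
                                 f"must match the canonical state structure {CANONICAL_SEQUELAE[self.code]}",
                                 tuple(self.sequelae)))
        for arm in ("course_screened", "course_unscreened"):
            curve = getattr(self, arm)
            if curve is not None:
                out.extend(curve.violations(prefix=f"{prefix}.{arm}"))
                extra = set(curve.p_onset) - set(self.sequelae)
                if extra:
                    out.append(Violation(f"{prefix}.{arm}.p_onset",
                                         "onset curves only for the disease's sequelae", sorted(extra)))
        return out


@dataclass
class UtilityTable:
    """Health-state utilities with optional low/high bounds for sensitivity analysis."""

    values: dict[str, float]
    bounds: dict[str, tuple[float, float]] = field(default_factory=dict)

    REQUIRED = ("NS", "DD", "ND", "MR", "RD", "Alive", "Dead")

    def violations(self, prefix: str = "utilities") -> list[Violation]:
        out = []
        for state in self.REQUIRED:
            if state not in self.values:
                out.append(Violation(f"{prefix}.{state}", "missing utility", None))
        for state, v in self.values.items():
            if not 0.0 <= v <= 1.0:
                out.append(Violation(f"{prefix}.{state}", "must lie in [0, 1]", v))
        if self.values.get("Alive") not in (None, 1.0):
            out.append(Violation(f"{prefix}.Alive", "healthy alive utility must be 1", self.values["Alive"]))
        if self.values.get("Dead") not in (None, 0.0):
            out.append(Violation(f"{prefix}.Dead", "dead utility must be 0", self.values["Dead"]))
        for state, (lo, hi) in self.bounds.items():
            base = self.values.get(state)
            if base is not None and not lo <= base <= hi:
                out.append(Violation(f"{prefix}.bounds.{state}", "bounds must bracket the mean", (lo, base, hi)))
        return out


@dataclass
class CostTable:
    """Non-assay cost parameters (2018 RMB).

    ``sequela_care`` is the annual care cost per sequela state; ``transport``
    and ``lost_productivity`` accrue annually to families of diseased
    children during confirmation/treatment/follow-up; ``program_fixed`` are
    fixed program costs per year and ``program_per_person`` per-person-year
    overheads of running the screening program.
    """

    sequela_care: dict[str, float]
    transport: float
    lost_productivity: float
    program_fixed: dict[str, float]
    program_per_person: dict[str, float]

    def program_cost_per_newborn(self, cohort_size: float) -> float:
        fixed = sum(self.program_fixed.values())
        return fixed / cohort_size + sum(self.program_per_person.values())

    def violations(self, prefix: str = "costs") -> list[Violation]:
        out = []
        for seq, v in self.sequela_care.items():
            if v < 0:
                out.append(Violation(f"{prefix}.sequela_care.{seq}", "must be >= 0", v))
        for attr in ("transport", "lost_productivity"):
            v = getattr(self, attr)
            if v < 0:
                out.append(Violation(f"{prefix}.{attr}", "must be >= 0", v))
        for group in ("program_fixed", "program_per_person"):
            for k, v in getattr(self, group).items():
                if v < 0:
                    out.append(Violation(f"{prefix}.{group}.{k}", "must be >= 0", v))
        return out


@dataclass
class EconSettings:
    """Economic and run settings.

    ``discount_timing`` selects mid-cycle ("mid", the default, consistent
    with the trapezoid half-cycle correction) or end-of-cycle ("end")
    discounting. ``unscreened_cost_onset`` controls when undetected patients
    start accruing treatment costs: ``"sequela"`` (at sequela onset, the
    default) or an integer age.
    """

    discount_rate: float = 0.03
    cohort_size: float = 200_000
    horizon: int = 82
    cycle_length: float = 1.0
    per_capita_gdp: float = 189_568.0
    icer_threshold: float = 568_704.0
    gov_share_screening: float = 0.80
    gov_share_treatment: float = 0.60
    bia_years: int = 10
    discount_timing: str = "mid"
    unscreened_cost_onset: str | int = "sequela"

    def violations(self, prefix: str = "econ") -> list[Violation]:
        out = []
        if not 0.0 <= self.discount_rate <= 1.0:
            out.append(Violation(f"{prefix}.discount_rate", "must lie in [0, 1]", self.discount_rate))
        if self.horizon < 1:
            out.append(Violation(f"{prefix}.horizon", "must be >= 1", self.horizon))
        if self.cohort_size <= 0:
            out.append(Violation(f"{prefix}.cohort_size", "must be > 0", self.cohort_size))
        for attr in ("gov_share_screening", "gov_share_treatment"):
            v = getattr(self, attr)
            if not 0.0 <= v <= 1.0:
                out.append(Violation(f"{prefix}.{attr}", "must lie in [0, 1]", v))
        if abs(self.icer_threshold - 3.0 * self.per_capita_gdp) > 0.5:
            out.append(Violation(f"{prefix}.icer_threshold",
                                 "must equal 3 x per-capita GDP", self.icer_threshold))
        if self.discount_timing not in ("mid", "end"):
            out.append(Violation(f"{prefix}.discount_timing", "must be 'mid' or 'end'", self.discount_timing))
        if self.bia_years < 1:
            out.append(Violation(f"{prefix}.bia_years", "must be >= 1", self.bia_years))
        return out


@dataclass
class ParameterSet:
    """The complete model input."""

    diseases: list[DiseaseSpec]
    assays: dict[str, AssaySpec]
    utilities: UtilityTable
    costs: CostTable
    econ: EconSettings
    name: str = "unnamed"

    def disease(self, code: str) -> DiseaseSpec:
        for d in self.diseases:
            if d.code == code:
                return d
        raise KeyError(f"unknown disease code {code!r}")

    @property
    def disease_codes(self) -> list[str]:
        return [d.code for d in self.diseases]

    def total_incidence(self, codes: Iterable[str] | None = None) -> float:
        codes = set(codes) if codes is not None else set(self.disease_codes)
        return sum(d.incidence for d in self.diseases if d.code in codes)

    def copy(self) -> "ParameterSet":
        return copy.deepcopy(self)

    def content_hash(self) -> str:
        """Stable digest of every numeric input, including course curves."""
        doc = parameter_set_to_dict(self, include_courses=True)
        blob = json.dumps(doc, sort_keys=True, separators=(",", ":")).encode()
        return hashlib.sha256(blob).hexdigest()


# ---------------------------------------------------------------------------
# operations


_RATIO_RE = re.compile(r"^\s*1\s*:\s*([0-9][0-9,]*(?:\.[0-9]+)?)\s*$")


def incidence_from_ratio(ratio_text: str) -> float:
    """Parse an incidence printed as ``"1:N"`` (comma separators allowed) to 1/N.

    >>> round(incidence_from_ratio("1:14,028"), 9)
    7.1286e-05
    """
    m = _RATIO_RE.match(str(ratio_text))
    if not m:
        raise ParameterError([Violation("incidence_ratio", "malformed ratio, expected '1:N'", ratio_text)])
    n = float(m.group(1).replace(",", ""))
    if n <= 0:
        raise ParameterError([Violation("incidence_ratio", "N must be > 0", ratio_text)])
    return 1.0 / n


def validate_parameter_set(ps: ParameterSet) -> list[Violation]:
    """Return all invariant violations (empty list means the set is valid)."""
    out: list[Violation] = []
    if not ps.diseases:
        out.append(Violation("diseases", "disease list must not be empty", 0))
    codes = [d.code for d in ps.diseases]
    dupes = {c for c in codes if codes.count(c) > 1}
    if dupes:
        out.append(Violation("diseases", "disease codes must be unique", sorted(dupes)))
    for i, d in enumerate(ps.diseases):
        out.extend(d.violations(prefix=f"diseases.{d.code or i}"))
    for name in ASSAY_NAMES:
        if name not in ps.assays:
            out.append(Violation(f"assays.{name}", "assay must be present", None))
    for name, assay in ps.assays.items():
        out.extend(assay.violations(prefix=f"assays.{name}"))
    out.extend(ps.utilities.violations())
    out.extend(ps.costs.violations())
    out.extend(ps.econ.violations())
    return out


def _require(doc: Mapping, key: str, path: str) -> Any:
    if key not in doc:
        raise ParameterError([Violation(f"{path}.{key}", "missing required key", None)])
    return doc[key]


def parameter_set_from_dict(doc: Mapping, fill_courses: bool = True) -> ParameterSet:
    """Build and validate a :class:`ParameterSet` from a configuration tree.

    If the document carries ``courses: packaged`` (and ``fill_courses`` is
    true), missing course curves are synthesized from the packaged course
    templates; ``courses: none`` leaves them unset. Raises
    :class:`ParameterError` listing every violation if validation fails.
    """
    assays = {}
    for name, a in _require(doc, "assays", "$").items():
        assays[name] = AssaySpec(
            name=name,
            sensitivity=float(_require(a, "sensitivity", f"assays.{name}")),
            specificity=float(_require(a, "specificity", f"assays.{name}")),
            screen_cost=float(_require(a, "screen_cost", f"assays.{name}")),
            confirm_cost=float(_require(a, "confirm_cost", f"assays.{name}")),
            followup_cost=float(_require(a, "followup_cost", f"assays.{name}")),
        )
    diseases = []
    for d in _require(doc, "diseases", "$"):
        code = str(_require(d, "code", "diseases[]"))
        diseases.append(DiseaseSpec(
            code=code,
            incidence=float(_require(d, "incidence", f"diseases.{code}")),
            sequelae=tuple(_require(d, "sequelae", f"diseases.{code}")),
            treatment_cost_0_5=float(_require(d, "treatment_cost_0_5", f"diseases.{code}")),
            treatment_cost_6_82=float(_require(d, "treatment_cost_6_82", f"diseases.{code}")),
            course_screened=CourseCurve.from_dict(d["course_screened"]) if "course_screened" in d else None,
            course_unscreened=CourseCurve.from_dict(d["course_unscreened"]) if "course_unscreened" in d else None,
            early_death_flag=d.get("early_death_flag"),
            incidence_assumed=bool(d.get("incidence_assumed", False)),
        ))
    util_doc = _require(doc, "utilities", "$")
    utilities = UtilityTable(
        values={k: float(v) for k, v in _require(util_doc, "values", "utilities").items()},
        bounds={k: (float(v[0]), float(v[1])) for k, v in util_doc.get("bounds", {}).items()},
    )
    cost_doc = _require(doc, "costs", "$")
    costs = CostTable(
        sequela_care={k: float(v) for k, v in _require(cost_doc, "sequela_care", "costs").items()},
        transport=float(_require(cost_doc, "transport", "costs")),
        lost_productivity=float(_require(cost_doc, "lost_productivity", "costs")),
        program_fixed={k: float(v) for k, v in _require(cost_doc, "program_fixed", "costs").items()},
        program_per_person={k: float(v) for k, v in _require(cost_doc, "program_per_person", "costs").items()},
    )
    econ_doc = dict(doc.get("econ", {}))
    known = {f.name for f in fields(EconSettings)}
    unknown = sorted(set(econ_doc) - known)
    if unknown:
        raise ParameterError([Violation(f"econ.{k}", "unknown setting", econ_doc[k]) for k in unknown])
    econ = EconSettings(**econ_doc)
    ps = ParameterSet(diseases=diseases, assays=assays, utilities=utilities,
                      costs=costs, econ=econ, name=str(doc.get("name", "unnamed")))

    if fill_courses and doc.get("courses") == "packaged":
        from . import course_synthesis  # lazy: course_synthesis imports this module

        library = course_synthesis.baseline_course_library(horizon=econ.horizon)
        for d in ps.diseases:
            if d.course_screened is None and (d.code, "screened") in library:
                d.course_screened = library[(d.code, "screened")]
            if d.course_unscreened is None and (d.code, "unscreened") in library:
                d.course_unscreened = library[(d.code, "unscreened")]

    violations = validate_parameter_set(ps)
    if violations:
        raise ParameterError(violations)
    return ps


def parameter_set_to_dict(ps: ParameterSet, include_courses: bool = True) -> dict:
    doc: dict[str, Any] = {
        "name": ps.name,
        "assays": {
            name: {
                "sensitivity": a.sensitivity, "specificity": a.specificity,
                "screen_cost": a.screen_cost, "confirm_cost": a.confirm_cost,
                "followup_cost": a.followup_cost,
            } for name, a in ps.assays.items()
        },
        "diseases": [],
        "utilities": {
            "values": dict(ps.utilities.values),
            "bounds": {k: [lo, hi] for k, (lo, hi) in ps.utilities.bounds.items()},
        },
        "costs": {
            "sequela_care": dict(ps.costs.sequela_care),
            "transport": ps.costs.transport,
            "lost_productivity": ps.costs.lost_productivity,
            "program_fixed": dict(ps.costs.program_fixed),
            "program_per_person": dict(ps.costs.program_per_person),
        },
        "econ": {f.name: getattr(ps.econ, f.name) for f in fields(EconSettings)},
    }
    for d in ps.diseases:
        dd: dict[str, Any] = {
            "code": d.code, "incidence": d.incidence, "sequelae": list(d.sequelae),
            "treatment_cost_0_5": d.treatment_cost_0_5,
            "treatment_cost_6_82": d.treatment_cost_6_82,
        }
        if d.early_death_flag is not None:
            dd["early_death_flag"] = d.early_death_flag
        if d.incidence_assumed:
            dd["incidence_assumed"] = True
        if include_courses:
            if d.course_screened is not None:
                dd["course_screened"] = d.course_screened.to_dict()
            if d.course_unscreened is not None:
                dd["course_unscreened"] = d.course_unscreened.to_dict()
        doc["diseases"].append(dd)
    return doc


def load_parameter_set(source: str | Path | Mapping, fill_courses: bool = True) -> ParameterSet:
    """Load a parameter set from a YAML path, a mapping, or the packaged baseline.

    ``source`` may be the well-known resource name ``"baseline/shenzhen_2018"``
    (or ``"shenzhen_2018"``), a filesystem path, or an already-parsed mapping.
    """
    if isinstance(source, Mapping):
        return parameter_set_from_dict(source, fill_courses=fill_courses)
    name = str(source)
    if name in (BASELINE_RESOURCE, f"baseline/{BASELINE_RESOURCE}"):
        text = resources.files("nbscea.data").joinpath(f"{BASELINE_RESOURCE}.yaml").read_text()
    else:
        text = Path(source).read_text()
    doc = yaml.safe_load(text)
    if not isinstance(doc, Mapping):
        raise ParameterError([Violation("$", "document must be a mapping", type(doc).__name__)])
    return parameter_set_from_dict(doc, fill_courses=fill_courses)


def save_parameter_set(ps: ParameterSet, path: str | Path, include_courses: bool = True) -> None:
    doc = parameter_set_to_dict(ps, include_courses=include_courses)
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def load_baseline(fill_courses: bool = True) -> ParameterSet:
    """The packaged Shenzhen 2018 baseline with the synthetic course library attached."""
    return load_parameter_set(BASELINE_RESOURCE, fill_courses=fill_courses)


# ---------------------------------------------------------------------------
# dotted-path overrides ("path=value" pairs, also accepted as CSV rows)


def apply_override(ps: ParameterSet, path: str, value: Any) -> None:
    """Set one parameter in place, addressed by a dotted path.

    Examples: ``econ.discount_rate``, ``assays.MSMS.screen_cost``,
    ``diseases.PKU.incidence``, ``utilities.values.NS``,
    ``costs.sequela_care.ND``.
    """
    parts = path.split(".")
    obj: Any = ps
    try:
        if parts[0] == "diseases":
            if len(parts) < 3:
                raise KeyError(path)
            obj = ps.disease(parts[1])
            parts = parts[2:]
        for part in parts[:-1]:
            obj = obj[part] if isinstance(obj, Mapping) else getattr(obj, part)
        _set_leaf(obj, parts[-1], path, value)
    except (KeyError, AttributeError) as exc:
        raise ParameterError([Violation(path, "unknown parameter path", str(exc))]) from exc


def _set_leaf(obj: Any, leaf: str, path: str, value: Any) -> None:
    if isinstance(obj, dict):
        if leaf not in obj:
            raise ParameterError([Violation(path, "unknown parameter path", leaf)])
        obj[leaf] = type(obj[leaf])(value) if isinstance(obj[leaf], (int, float)) else value
    else:
        if not hasattr(obj, leaf):
            raise ParameterError([Violation(path, "unknown parameter path", leaf)])
        current = getattr(obj, leaf)
        if isinstance(current, bool):
            value = bool(value)
        elif isinstance(current, (int, float)):
            value = type(current)(float(value))
        setattr(obj, leaf, value)


def apply_overrides(ps: ParameterSet, overrides: Mapping[str, Any] | Iterable[tuple[str, Any]]) -> None:
    items = overrides.items() if isinstance(overrides, Mapping) else overrides
    for path, value in items:
        apply_override(ps, path, value)
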