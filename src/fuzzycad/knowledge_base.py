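"""The canonical coronary-artery-lesion knowledge base.

Four anatomical lesion factors, each a linguistic variable with five terms
(L, LA, A, HA, H) given by published spline-linear membership functions, and
a base of fourteen weighted if-then rules mapping term combinations to the
four clinical forms of coronary artery disease:

* I   — NSTEMI, myocardial infarction without ST-segment elevation
* II  — UAP, unstable angina pectoris
* III — STEMI, myocardial infarction with ST-segment elevation
* IV  — StAP, stable angina pectoris

The factors (severity scores, unitless):

* X1 — presence of atherosclerotic plaques in the basin of the diagonal
  branch or left anterior descending artery (range 1.83–2.76)
* X2 — presence of hemodynamically significant stenosis in the same basin
  (1.74–3.0)
* X3 — presence of hemodynamically significant stenosis in the trunk of the
  right coronary artery (1.0–2.35)
* X4 — absence of hemodynamically significant stenosis of the coronary
  arteries (2.07–4.67)

:func:`closed_form_class_membership` hand-codes each class's
union-of-conjunctions expression directly, without touching the generic rule
loop, and serves as an independent oracle for the inference engine.
"""

from __future__ import annotations

import enum
import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence, Union

from .fuzzy_core import (
    BellMF,
    CombinerConfig,
    ContractError,
    DomainError,
    LinearSegment,
    LinguisticVariable,
    MembershipFunction,
    PiecewiseLinearMF,
    TermLabel,
    check_variable_consistency,
    evaluate_mf,
)

SCHEMA_VERSION = 1

FACTOR_IDS = ("X1", "X2", "X3", "X4")

#: Empirical min/max of each factor over the study cohort.
FACTOR_DOMAINS: dict[str, tuple[float, float]] = {
    "X1": (1.83, 2.76),
    "X2": (1.74, 3.0),
    "X3": (1.0, 2.35),
    "X4": (2.07, 4.67),
}

FACTOR_DESCRIPTIONS: dict[str, str] = {
    "X1": "Presence of a/p on the territory of DG or LAD LCA",
    "X2": "Presence of HSS on the territory of DG or LAD LCA",
    "X3": "Presence of HSS in the trunk of the RCA",
    "X4": "Absence of HSS CA",
}


class ValidationError(ValueError):
    """A knowledge-base document violates the schema or its invariants."""


class DiagnosisClass(enum.IntEnum):
    """The four clinical forms of CAD, indexed I-IV."""

    I = 1
    II = 2
    III = 3
    IV = 4

    @property
    def clinical_name(self) -> str:
        return _CLASS_NAMES[self]

    @classmethod
    def from_string(cls, s: str) -> "DiagnosisClass":
        s = s.strip()
        try:
            return cls[s]
        except KeyError:
            pass
        for k, name in _CLASS_NAMES.items():
            if name == s:
                return k
        raise ContractError(
            f"unknown diagnosis class {s!r}; expected I-IV or one of "
            f"{list(_CLASS_NAMES.values())}"
        )


_CLASS_NAMES = {
    DiagnosisClass.I: "NSTEMI",
    DiagnosisClass.II: "UAP",
    DiagnosisClass.III: "STEMI",
    DiagnosisClass.IV: "StAP",
}


@dataclass(frozen=True)
class FactorDefinition:
    id: str
    description: str
    domain: tuple[float, float]


@dataclass(frozen=True)
class Rule:
    """One if-then rule: a complete antecedent over all four factors.

    ``weight`` scales the rule's activation (weight x t-norm of antecedent
    degrees); the published rule base is unweighted, i.e. all weights are 1,
    and weights below 1 arise only from tuning.
    """

    antecedent: Mapping[str, TermLabel]
    consequent: DiagnosisClass
    weight: float = 1.0

    def __post_init__(self) -> None:
        missing = [f for f in FACTOR_IDS if f not in self.antecedent]
        if missing:
            raise ContractError(f"rule antecedent missing factors {missing}")
        if not (0.0 <= self.weight <= 1.0):
            raise ContractError(f"rule weight {self.weight} outside [0, 1]")
        object.__setattr__(self, "antecedent", dict(self.antecedent))

    def antecedent_key(self) -> tuple:
        return tuple(self.antecedent[f] for f in FACTOR_IDS)


@dataclass(frozen=True)
class KnowledgeBase:
    variables: Mapping[str, LinguisticVariable]
    rules: tuple[Rule, ...]
    metadata: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "variables", dict(self.variables))
        object.__setattr__(self, "rules", tuple(self.rules))
        for rule in self.rules:
            for fid in rule.antecedent:
                if fid not in self.variables:
                    raise ValidationError(
                        f"rule references undefined factor {fid!r}"
                    )

    def rules_for(self, cls: DiagnosisClass) -> tuple[Rule, ...]:
        return tuple(r for r in self.rules if r.consequent == cls)

    def referenced_terms(self) -> set[tuple[str, TermLabel]]:
        """(factor, term) pairs that appear in at least one rule antecedent."""
        return {
            (fid, label)
            for rule in self.rules
            for fid, label in rule.antecedent.items()
        }


# ---------------------------------------------------------------------------
# The published membership functions, transcribed as (slope, intercept) pieces
# ---------------------------------------------------------------------------
# Each entry: factor -> term -> [(lower, upper, slope, intercept), ...]
# Pieces are half-open [lower; upper) except the last, which is closed.

_MF_TABLE: dict[str, dict[TermLabel, list[tuple[float, float, float, float]]]] = {
    "X1": {
        TermLabel.L: [
            (1.83, 2.06, -2.17, 4.97),
            (2.06, 2.76, -0.71, 1.97),
        ],
        TermLabel.LA: [
            (1.83, 2.06, 2.17, -3.48),
            (2.06, 2.30, -2.08, 5.29),
            (2.30, 2.76, -1.09, 3.0),
        ],
        TermLabel.A: [
            (1.83, 2.30, 2.13, -3.89),
            (2.30, 2.76, -2.17, 6.0),
        ],
        TermLabel.HA: [
            (1.83, 2.30, 1.06, -1.94),
            (2.30, 2.53, 2.17, -4.5),
            (2.53, 2.76, -2.17, 6.5),
        ],
        TermLabel.H: [
            (1.83, 2.53, 0.71, -1.31),
            (2.53, 2.76, 2.17, -5.0),
        ],
    },
    "X2": {
        TermLabel.L: [
            (1.74, 2.06, -1.56, 3.72),
            (2.06, 3.0, -0.53, 1.6),
        ],
        TermLabel.LA: [
            (1.74, 2.06, 1.56, -2.22),
            (2.06, 2.37, -1.61, 4.3),
            (2.37, 3.0, -0.79, 2.38),
        ],
        TermLabel.A: [
            (1.74, 2.30, 1.59, -2.76),
            (2.30, 3.0, -1.59, 4.76),
        ],
        TermLabel.HA: [
            (1.74, 2.37, 0.79, -1.38),
            (2.37, 2.69, 1.56, -3.2),
            (2.69, 3.0, -1.61, 5.34),
        ],
        TermLabel.H: [
            (1.74, 2.53, 0.53, -0.92),
            (2.53, 3.0, 1.61, -3.84),
        ],
    },
    "X3": {
        TermLabel.L: [
            (1.0, 1.34, -1.47, 2.47),
            (1.34, 2.35, -0.495, 1.16),
        ],
        TermLabel.LA: [
            (1.0, 1.34, 1.47, -0.97),
            (1.34, 1.68, -1.47, 2.97),
            (1.68, 2.35, -0.74, 1.75),
        ],
        TermLabel.A: [
            (1.0, 1.68, 1.47, -1.47),
            (1.68, 2.35, -1.49, 3.5),
        ],
        TermLabel.HA: [
            (1.0, 1.68, 0.73, -0.73),
            (1.68, 2.02, 1.47, -1.97),
            (2.02, 2.35, -1.52, 4.06),
        ],
        TermLabel.H: [
            (1.0, 2.02, 0.49, -0.49),
            (2.02, 2.35, 1.52, -2.56),
        ],
    },
    "X4": {
        TermLabel.L: [
            (2.07, 2.72, -0.769, 2.59),
            (2.72, 4.67, -0.26, 1.197),
        ],
        TermLabel.LA: [
            (2.07, 2.72, 0.769, -1.09),
            (2.72, 3.37, -0.769, 3.09),
            (3.37, 4.67, -0.38, 1.796),
        ],
        TermLabel.A: [
            (2.07, 3.37, 0.769, -1.59),
            (3.37, 4.67, -0.769, 3.59),
        ],
        TermLabel.HA: [
            (2.07, 3.37, 0.38, -0.796),
            (3.37, 4.02, 0.769, -2.09),
            (4.02, 4.67, -0.769, 4.09),
        ],
        TermLabel.H: [
            (2.07, 4.02, 0.25, -0.53),
            (4.02, 4.67, 0.769, -2.59),
        ],
    },
}

# The rule base: (consequent, (X1, X2, X3, X4) terms).  Three rules for
# class I, four for II, three for III, four for IV — fourteen in total.
_L, _LA, _A, _HA, _H = TermLabel
_RULE_TABLE: list[tuple[DiagnosisClass, tuple[TermLabel, ...]]] = [
    (DiagnosisClass.I, (_HA, _A, _L, _A)),
    (DiagnosisClass.I, (_HA, _HA, _L, _A)),
    (DiagnosisClass.I, (_HA, _HA, _L, _HA)),
    (DiagnosisClass.II, (_LA, _A, _L, _H)),
    (DiagnosisClass.II, (_A, _HA, _L, _LA)),
    (DiagnosisClass.II, (_LA, _HA, _L, _LA)),
    (DiagnosisClass.II, (_A, _L, _L, _LA)),
    (DiagnosisClass.III, (_HA, _LA, _HA, _HA)),
    (DiagnosisClass.III, (_HA, _LA, _HA, _H)),
    (DiagnosisClass.III, (_L, _A, _HA, _H)),
    (DiagnosisClass.IV, (_L, _L, _A, _A)),
    (DiagnosisClass.IV, (_LA, _L, _A, _A)),
    (DiagnosisClass.IV, (_L, _LA, _LA, _LA)),
    (DiagnosisClass.IV, (_LA, _LA, _LA, _LA)),
]


def build_default_knowledge_base() -> KnowledgeBase:
    """The published model: 20 piecewise-linear terms and 14 unit-weight rules."""
    variables = {}
    for fid in FACTOR_IDS:
        domain = FACTOR_DOMAINS[fid]
        terms = {}
        for label, pieces in _MF_TABLE[fid].items():
            segments = [
                LinearSegment(
                    lower=lo,
                    upper=up,
                    slope=slope,
                    intercept=intercept,
                    upper_closed=(i == len(pieces) - 1),
                )
                for i, (lo, up, slope, intercept) in enumerate(pieces)
            ]
            terms[label] = PiecewiseLinearMF(segments=tuple(segments), domain=domain)
        variables[fid] = LinguisticVariable(
            factor_id=fid,
            description=FACTOR_DESCRIPTIONS[fid],
            domain=domain,
            terms=terms,
        )
    rules = tuple(
        Rule(
            antecedent=dict(zip(FACTOR_IDS, terms)),
            consequent=consequent,
            weight=1.0,
        )
        for consequent, terms in _RULE_TABLE
    )
    return KnowledgeBase(
        variables=variables,
        rules=rules,
        metadata="default coronary-artery-lesion knowledge base",
    )


# ---------------------------------------------------------------------------
# Closed-form oracle
# ---------------------------------------------------------------------------

def closed_form_class_membership(
    x: Sequence[float],
    cls: DiagnosisClass,
    config: CombinerConfig = CombinerConfig(),
    kb: KnowledgeBase | None = None,
) -> float:
    """Hand-coded class membership: each class's union of conjunctions.

    Written out term by term, one explicit expression per class, independent
    of the generic rule iteration in :mod:`fuzzycad.inference`; intended as
    an oracle to check the engine against.  With min/max combiners and unit
    weights this is the published model verbatim.
    """
    if len(x) != 4:
        raise ContractError(f"expected a 4-vector, got {len(x)} values")
    kb = kb if kb is not None else _default_kb()
    x1, x2, x3, x4 = (float(v) for v in x)

    def mu(fid: str, label: TermLabel, value: float) -> float:
        return evaluate_mf(kb.variables[fid].terms[label], value, config.out_of_range)

    def AND(*vals: float) -> float:
        if config.t_norm == "min":
            return min(vals)
        return math.prod(vals)

    def OR(*vals: float) -> float:
        if config.s_norm == "max":
            return max(vals)
        return 1.0 - math.prod(1.0 - v for v in vals)

    if cls == DiagnosisClass.I:
        return OR(
            AND(mu("X1", _HA, x1), mu("X2", _A, x2), mu("X3", _L, x3), mu("X4", _A, x4)),
            AND(mu("X1", _HA, x1), mu("X2", _HA, x2), mu("X3", _L, x3), mu("X4", _A, x4)),
            AND(mu("X1", _HA, x1), mu("X2", _HA, x2), mu("X3", _L, x3), mu("X4", _HA, x4)),
        )
    if cls == DiagnosisClass.II:
        return OR(
            AND(mu("X1", _LA, x1), mu("X2", _A, x2), mu("X3", _L, x3), mu("X4", _H, x4)),
            AND(mu("X1", _A, x1), mu("X2", _HA, x2), mu("X3", _L, x3), mu("X4", _LA, x4)),
            AND(mu("X1", _LA, x1), mu("X2", _HA, x2), mu("X3", _L, x3), mu("X4", _LA, x4)),
            AND(mu("X1", _A, x1), mu("X2", _L, x2), mu("X3", _L, x3), mu("X4", _LA, x4)),
        )
    if cls == DiagnosisClass.III:
        return OR(
            AND(mu("X1", _HA, x1), mu("X2", _LA, x2), mu("X3", _HA, x3), mu("X4", _HA, x4)),
            AND(mu("X1", _HA, x1), mu("X2", _LA, x2), mu("X3", _HA, x3), mu("X4", _H, x4)),
            AND(mu("X1", _L, x1), mu("X2", _A, x2), mu("X3", _HA, x3), mu("X4", _H, x4)),
        )
    if cls == DiagnosisClass.IV:
        return OR(
            AND(mu("X1", _L, x1), mu("X2", _L, x2), mu("X3", _A, x3), mu("X4", _A, x4)),
            AND(mu("X1", _LA, x1), mu("X2", _L, x2), mu("X3", _A, x3), mu("X4", _A, x4)),
            AND(mu("X1", _L, x1), mu("X2", _LA, x2), mu("X3", _LA, x3), mu("X4", _LA, x4)),
            AND(mu("X1", _LA, x1), mu("X2", _LA, x2), mu("X3", _LA, x3), mu("X4", _LA, x4)),
        )
    raise ContractError(f"unknown class {cls!r}")


_DEFAULT_KB: KnowledgeBase | None = None


def _default_kb() -> KnowledgeBase:
    global _DEFAULT_KB
    if _DEFAULT_KB is None:
        _DEFAULT_KB = build_default_knowledge_base()
    return _DEFAULT_KB


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def _mf_to_dict(mf: MembershipFunction) -> dict:
    if isinstance(mf, BellMF):
        return {"kind": "bell", "b": mf.b, "c": mf.c}
    return {
        "kind": "piecewise_linear",
        "segments": [
            {
                "lower": s.lower,
                "upper": s.upper,
                "slope": s.slope,
                "intercept": s.intercept,
                "upper_closed": s.upper_closed,
            }
            for s in mf.segments
        ],
    }


def kb_to_dict(kb: KnowledgeBase) -> dict:
    return {
        "schema_version": SCHEMA_VERSION,
        "metadata": kb.metadata,
        "factors": [
            {
                "id": fid,
                "description": var.description,
                "domain": list(var.domain),
                "terms": {
                    label.name: _mf_to_dict(var.terms[label]) for label in TermLabel
                },
            }
            for fid, var in kb.variables.items()
        ],
        "rules": [
            {
                "antecedent": {
                    fid: rule.antecedent[fid].name for fid in FACTOR_IDS
                },
                "consequent": rule.consequent.name,
                "weight": rule.weight,
            }
            for rule in kb.rules
        ],
    }


def save_knowledge_base(kb: KnowledgeBase, path: str | Path) -> None:
    """Write the knowledge base as JSON (the on-disk format)."""
    Path(path).write_text(json.dumps(kb_to_dict(kb), indent=2) + "\n")


def _require(cond: bool, path: str, msg: str) -> None:
    if not cond:
        raise ValidationError(f"{path}: {msg}")


def _reject_unknown(obj: dict, allowed: set[str], path: str) -> None:
    unknown = set(obj) - allowed
    _require(not unknown, path, f"unknown fields {sorted(unknown)}")


def _mf_from_dict(obj: dict, domain: tuple[float, float], path: str) -> MembershipFunction:
    _require(isinstance(obj, dict), path, "term must be an object")
    kind = obj.get("kind")
    if kind == "bell":
        _reject_unknown(obj, {"kind", "b", "c"}, path)
        _require("b" in obj and "c" in obj, path, "bell needs fields b and c")
        try:
            return BellMF(b=float(obj["b"]), c=float(obj["c"]))
        except ContractError as e:
            raise ValidationError(f"{path}: {e}") from None
    if kind == "piecewise_linear":
        _reject_unknown(obj, {"kind", "segments"}, path)
        segs_obj = obj.get("segments")
        _require(isinstance(segs_obj, list) and segs_obj, path, "needs segments")
        segments = []
        for i, s in enumerate(segs_obj):
            spath = f"{path}.segments[{i}]"
            _require(isinstance(s, dict), spath, "segment must be an object")
            _reject_unknown(
                s, {"lower", "upper", "slope", "intercept", "upper_closed"}, spath
            )
            for key in ("lower", "upper", "slope", "intercept"):
                _require(key in s, spath, f"missing field {key!r}")
            try:
                segments.append(
                    LinearSegment(
                        lower=float(s["lower"]),
                        upper=float(s["upper"]),
                        slope=float(s["slope"]),
                        intercept=float(s["intercept"]),
                        upper_closed=bool(s.get("upper_closed", False)),
                    )
                )
            except ContractError as e:
                raise ValidationError(f"{spath}: {e}") from None
        try:
            return PiecewiseLinearMF(segments=tuple(segments), domain=domain)
        except ContractError as e:
            raise ValidationError(f"{path}: {e}") from None
    raise ValidationError(f"{path}: unknown membership kind {kind!r}")


def kb_from_dict(doc: dict) -> KnowledgeBase:
    _require(isinstance(doc, dict), "$", "document must be an object")
    _reject_unknown(doc, {"schema_version", "metadata", "factors", "rules"}, "$")
    _require(
        doc.get("schema_version") == SCHEMA_VERSION,
        "$.schema_version",
        f"expected {SCHEMA_VERSION}, got {doc.get('schema_version')!r}",
    )
    factors_obj = doc.get("factors")
    _require(isinstance(factors_obj, list), "$.factors", "must be a list")

    variables: dict[str, LinguisticVariable] = {}
    for i, f in enumerate(factors_obj):
        fpath = f"$.factors[{i}]"
        _require(isinstance(f, dict), fpath, "factor must be an object")
        _reject_unknown(f, {"id", "description", "domain", "terms"}, fpath)
        fid = f.get("id")
        _require(fid in FACTOR_IDS, f"{fpath}.id", f"unknown factor id {fid!r}")
        _require(fid not in variables, f"{fpath}.id", f"duplicate factor {fid!r}")
        dom = f.get("domain")
        _require(
            isinstance(dom, list) and len(dom) == 2 and dom[0] < dom[1],
            f"{fpath}.domain",
            f"must be [min, max] with min < max, got {dom!r}",
        )
        domain = (float(dom[0]), float(dom[1]))
        terms_obj = f.get("terms")
        _require(isinstance(terms_obj, dict), f"{fpath}.terms", "must be an object")
        _reject_unknown(terms_obj, {t.name for t in TermLabel}, f"{fpath}.terms")
        missing = [t.name for t in TermLabel if t.name not in terms_obj]
        _require(not missing, f"{fpath}.terms", f"missing terms {missing}")
        terms = {
            TermLabel[name]: _mf_from_dict(
                terms_obj[name], domain, f"{fpath}.terms.{name}"
            )
            for name in terms_obj
        }
        variables[fid] = LinguisticVariable(
            factor_id=fid,
            description=str(f.get("description", "")),
            domain=domain,
            terms=terms,
        )
    missing_factors = [fid for fid in FACTOR_IDS if fid not in variables]
    _require(not missing_factors, "$.factors", f"missing factors {missing_factors}")

    rules_obj = doc.get("rules")
    _require(isinstance(rules_obj, list) and rules_obj, "$.rules", "must be a non-empty list")
    rules: list[Rule] = []
    for i, r in enumerate(rules_obj):
        rpath = f"$.rules[{i}]"
        _require(isinstance(r, dict), rpath, "rule must be an object")
        _reject_unknown(r, {"antecedent", "consequent", "weight"}, rpath)
        ant_obj = r.get("antecedent")
        _require(isinstance(ant_obj, dict), f"{rpath}.antecedent", "must be an object")
        for fid in ant_obj:
            _require(
                fid in FACTOR_IDS,
                f"{rpath}.antecedent",
                f"unknown factor {fid!r}",
            )
        missing = [fid for fid in FACTOR_IDS if fid not in ant_obj]
        _require(not missing, f"{rpath}.antecedent", f"missing factors {missing}")
        antecedent = {}
        for fid, tname in ant_obj.items():
            _require(
                isinstance(tname, str) and tname in TermLabel.__members__,
                f"{rpath}.antecedent.{fid}",
                f"unknown term {tname!r}",
            )
            antecedent[fid] = TermLabel[tname]
        cname = r.get("consequent")
        _require(
            isinstance(cname, str) and cname in DiagnosisClass.__members__,
            f"{rpath}.consequent",
            f"unknown class {cname!r}",
        )
        weight = float(r.get("weight", 1.0))
        _require(
            0.0 <= weight <= 1.0, f"{rpath}.weight", f"weight {weight} outside [0, 1]"
        )
        rules.append(
            Rule(
                antecedent=antecedent,
                consequent=DiagnosisClass[cname],
                weight=weight,
            )
        )
    return KnowledgeBase(
        variables=variables,
        rules=tuple(rules),
        metadata=str(doc.get("metadata", "")),
    )


def load_knowledge_base(path: str | Path) -> KnowledgeBase:
    """Load a knowledge base from JSON (or YAML, by extension)."""
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        import yaml

        doc = yaml.safe_load(text)
    else:
        doc = json.loads(text)
    return kb_from_dict(doc)


# ---------------------------------------------------------------------------
# Validation diagnostics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KBDiagnostics:
    duplicate_rules: tuple[tuple[int, int], ...]
    uncovered_classes: tuple[DiagnosisClass, ...]
    unused_factors: tuple[str, ...]
    variable_reports: Mapping[str, "object"]  # factor_id -> ConsistencyReport
    warnings: tuple[str, ...]

    def to_dict(self) -> dict:
        return {
            "duplicate_rules": [list(p) for p in self.duplicate_rules],
            "uncovered_classes": [c.name for c in self.uncovered_classes],
            "unused_factors": list(self.unused_factors),
            "variable_reports": {
                fid: rep.to_dict() for fid, rep in self.variable_reports.items()
            },
            "warnings": list(self.warnings),
        }


def validate_knowledge_base(kb: KnowledgeBase, grid_step: float = 1e-3) -> KBDiagnostics:
    """Structural and numerical diagnostics; never raises on a loadable KB."""
    warnings: list[str] = []

    seen: dict[tuple, int] = {}
    duplicates: list[tuple[int, int]] = []
    for i, rule in enumerate(kb.rules):
        key = (rule.consequent,) + rule.antecedent_key()
        if key in seen:
            duplicates.append((seen[key], i))
            warnings.append(f"rules {seen[key]} and {i} are duplicates")
        else:
            seen[key] = i

    uncovered = tuple(
        cls for cls in DiagnosisClass if not any(r.consequent == cls for r in kb.rules)
    )
    for cls in uncovered:
        warnings.append(f"class {cls.name} has no rules (uncovered class)")

    if len(kb.rules) != len(_RULE_TABLE):
        warnings.append(
            f"rule count {len(kb.rules)} differs from the canonical "
            f"{len(_RULE_TABLE)}; class coverage may have changed"
        )

    used = {fid for rule in kb.rules for fid in rule.antecedent}
    unused = tuple(fid for fid in kb.variables if fid not in used)
    for fid in unused:
        warnings.append(f"factor {fid} is unused by every rule")

    reports = {
        fid: check_variable_consistency(var, grid_step=grid_step)
        for fid, var in kb.variables.items()
    }
    return KBDiagnostics(
        duplicate_rules=tuple(duplicates),
        uncovered_classes=uncovered,
        unused_factors=unused,
        variable_reports=reports,
        warnings=tuple(warnings),
    )
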