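"""Mamdani-style decision algorithm over the rule base.

For one patient the algorithm runs in four steps: fix the factor values,
fuzzify (evaluate all 20 term memberships), compose per-class memberships
(rule activation = weight x t-norm over the four antecedent degrees; class
membership = s-norm over the class's rule activations), and decide by the
maximal class membership.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .fuzzy_core import (
    CombinerConfig,
    ContractError,
    DomainError,
    TermLabel,
    combine_and,
    combine_or,
    evaluate_mf,
)
from .knowledge_base import FACTOR_IDS, DiagnosisClass, KnowledgeBase, Rule

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PatientRecord:
    """One observation: the four anatomical-lesion factor scores."""

    x: Mapping[str, float]
    id: str | None = None

    def __post_init__(self) -> None:
        missing = [f for f in FACTOR_IDS if f not in self.x]
        if missing:
            raise ContractError(f"patient {self.id!r} missing factors {missing}")
        for fid in FACTOR_IDS:
            v = float(self.x[fid])
            if v != v or v in (float("inf"), float("-inf")):
                raise ContractError(f"patient {self.id!r}: non-finite {fid}={v}")
        object.__setattr__(self, "x", {f: float(self.x[f]) for f in FACTOR_IDS})

    @classmethod
    def from_values(
        cls, x1: float, x2: float, x3: float, x4: float, id: str | None = None
    ) -> "PatientRecord":
        return cls(x={"X1": x1, "X2": x2, "X3": x3, "X4": x4}, id=id)

    def as_vector(self) -> tuple[float, ...]:
        return tuple(self.x[f] for f in FACTOR_IDS)


@dataclass(frozen=True)
class FuzzificationMatrix:
    """All 4 x 5 term membership degrees for one patient."""

    degrees: Mapping[tuple[str, TermLabel], float]

    def __post_init__(self) -> None:
        expected = {(f, t) for f in FACTOR_IDS for t in TermLabel}
        if set(self.degrees) != expected:
            raise ContractError("fuzzification matrix must hold all 20 cells")
        for key, d in self.degrees.items():
            if not (0.0 <= d <= 1.0):
                raise ContractError(f"cell {key}: degree {d} outside [0, 1]")
        object.__setattr__(self, "degrees", dict(self.degrees))

    def __getitem__(self, key: tuple[str, TermLabel]) -> float:
        return self.degrees[key]


@dataclass(frozen=True)
class InferenceResult:
    memberships: Mapping[DiagnosisClass, float]
    decision: DiagnosisClass
    margin: float
    tie: bool
    argmax_classes: tuple[DiagnosisClass, ...]
    winning_rule: Rule | None = None
    warnings: tuple[str, ...] = ()
    patient_id: str | None = None


def fuzzify(
    patient: PatientRecord,
    kb: KnowledgeBase,
    config: CombinerConfig = CombinerConfig(),
) -> FuzzificationMatrix:
    """Evaluate every term of every factor at the patient's values.

    Under the default ``out_of_range='error'`` policy a value outside its
    factor's empirical range raises :class:`DomainError` naming the factor.
    """
    degrees = {}
    for fid in FACTOR_IDS:
        var = kb.variables[fid]
        value = patient.x[fid]
        for label in TermLabel:
            try:
                degrees[(fid, label)] = evaluate_mf(
                    var.terms[label], value, config.out_of_range
                )
            except DomainError:
                raise DomainError(
                    f"patient {patient.id!r}: {fid}={value} outside domain "
                    f"{list(var.domain)}"
                ) from None
    return FuzzificationMatrix(degrees=degrees)


def class_memberships(
    patient: PatientRecord,
    kb: KnowledgeBase,
    config: CombinerConfig = CombinerConfig(),
) -> dict[DiagnosisClass, float]:
    """Per-class membership degrees mu_d1..mu_d4 for one patient."""
    matrix = fuzzify(patient, kb, config)
    out: dict[DiagnosisClass, float] = {}
    for cls in DiagnosisClass:
        rules = kb.rules_for(cls)
        if not rules:
            raise ContractError(f"class {cls.name} has no rules")
        activations = [
            rule.weight
            * combine_and(
                [matrix[(fid, rule.antecedent[fid])] for fid in FACTOR_IDS],
                config.t_norm,
            )
            for rule in rules
        ]
        out[cls] = combine_or(activations, config.s_norm)
    return out


def decide(
    memberships: Mapping[DiagnosisClass, float],
    tie_break: str = "lowest_index",
    on_no_fire: str = "warn",
) -> InferenceResult:
    """Pick the class of maximal membership.

    Ties go to the lowest class index (I before II ...) and are flagged.
    When no rule fired at all (every membership zero) the result defaults to
    class I with a warning — or raises, with ``on_no_fire='error'``.
    """
    missing = [c.name for c in DiagnosisClass if c not in memberships]
    if missing:
        raise ContractError(f"memberships missing classes {missing}")
    values = {}
    for cls in DiagnosisClass:
        v = float(memberships[cls])
        if v != v or not (0.0 <= v <= 1.0):
            raise ContractError(f"class {cls.name}: degree {v} invalid")
        values[cls] = v

    top = max(values.values())
    argmax = tuple(c for c in DiagnosisClass if values[c] == top)
    decision = argmax[0]
    others = [values[c] for c in DiagnosisClass if c != decision]
    margin = top - max(others)
    tie = len(argmax) > 1

    warnings: list[str] = []
    if top == 0.0:
        if on_no_fire == "error":
            raise ContractError("no rule fired: all class memberships are zero")
        warnings.append("no rule fired")
        logger.warning("no rule fired: all class memberships are zero")
    if tie_break == "report_all":
        reported = argmax
    else:
        reported = (decision,)
    return InferenceResult(
        memberships=values,
        decision=decision,
        margin=margin,
        tie=tie,
        argmax_classes=argmax if tie_break == "report_all" else reported,
        warnings=tuple(warnings),
    )


def classify_patient(
    patient: PatientRecord,
    kb: KnowledgeBase,
    config: CombinerConfig = CombinerConfig(),
    on_no_fire: str = "warn",
) -> InferenceResult:
    """Full pipeline for one patient; also reports the winning rule."""
    memberships = class_memberships(patient, kb, config)
    result = decide(memberships, config.tie_break, on_no_fire)

    matrix = fuzzify(patient, kb, config)
    winning, best = None, -1.0
    for rule in kb.rules_for(result.decision):
        act = rule.weight * combine_and(
            [matrix[(fid, rule.antecedent[fid])] for fid in FACTOR_IDS],
            config.t_norm,
        )
        if act > best:
            winning, best = rule, act
    return InferenceResult(
        memberships=result.memberships,
        decision=result.decision,
        margin=result.margin,
        tie=result.tie,
        argmax_classes=result.argmax_classes,
        winning_rule=winning,
        warnings=result.warnings,
        patient_id=patient.id,
    )


def infer_cohort(
    patients: Sequence[PatientRecord],
    kb: KnowledgeBase,
    config: CombinerConfig = CombinerConfig(),
    labels: Sequence[DiagnosisClass] | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Classify a cohort; optionally score agreement against labels.

    Returns a results table (one row per patient: memberships, decision,
    margin, tie, warnings) and a summary dict with, when labels are given,
    the agreement fraction and a per-class confusion table.
    """
    if len(patients) == 0:
        raise ContractError("empty cohort")
    if labels is not None and len(labels) != len(patients):
        raise ContractError("labels must match patients one-to-one")

    rows = []
    for patient in patients:
        res = classify_patient(patient, kb, config)
        rows.append(
            {
                "id": patient.id,
                **{f"x{i+1}": patient.x[fid] for i, fid in enumerate(FACTOR_IDS)},
                **{
                    f"mu_{cls.name}": res.memberships[cls] for cls in DiagnosisClass
                },
                "decision": res.decision.name,
                "margin": res.margin,
                "tie": res.tie,
                "warnings": ";".join(res.warnings),
            }
        )
    table = pd.DataFrame(rows)

    summary: dict = {"n": len(patients)}
    if labels is not None:
        decided = table["decision"].tolist()
        truth = [c.name for c in labels]
        agreement = sum(d == t for d, t in zip(decided, truth)) / len(truth)
        confusion = (
            pd.crosstab(
                pd.Series(truth, name="label"),
                pd.Series(decided, name="decision"),
            )
            .reindex(
                index=[c.name for c in DiagnosisClass],
                columns=[c.name for c in DiagnosisClass],
                fill_value=0,
            )
        )
        summary["agreement"] = agreement
        summary["confusion"] = confusion
    return table, summary
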