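"""Seeded synthetic cohorts with the statistical structure of the study.

The study cohort comprised 165 patients in four clinical groups — 90 NSTEMI,
25 UAP, 25 STEMI and 25 StAP — with each group's four lesion-factor scores
summarised as mean ± standard error of the mean, and factor ranges given as
empirical min/max.  The generator draws each factor independently from a
truncated normal with per-record standard deviation ``sd = se * sqrt(n)``
(the ± is read as SEM), truncated to the factor's range.  Truncation shifts
the mean of a normal toward the centre of the window, so the location
parameter is calibrated (by root finding) until the truncated
distribution's mean equals the printed group mean; without this the
empirical group means would be biased and could not converge to the
printed values.  A uniform alternative (range-bounded, ignoring the group
means) is provided for sensitivity checks.

A degenerate ``se = 0`` (the UAP group's X3 score, printed as 1.00 ± 0)
yields the constant value.

Labels attached to generated records are the generating group — not a claim
that the fuzzy engine reproduces them; agreement is something to measure,
never to assert.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import optimize, stats

from .fuzzy_core import ContractError
from .knowledge_base import FACTOR_DOMAINS, FACTOR_IDS, DiagnosisClass
from .inference import PatientRecord


class GenerationError(ValueError):
    """The sampling specification cannot produce values in the domain."""


#: Per-group (class, n, per-factor mean, per-factor SEM) of the study cohort.
_GROUP_TABLE = [
    (DiagnosisClass.I, 90, (2.57, 2.42, 2.23, 3.66), (0.07, 0.18, 0.12, 0.20)),
    (DiagnosisClass.II, 25, (2.15, 2.50, 1.00, 2.50), (0.13, 0.50, 0.00, 0.43)),
    (DiagnosisClass.III, 25, (2.64, 2.08, 2.11, 4.32), (0.12, 0.23, 0.14, 0.35)),
    (DiagnosisClass.IV, 25, (2.00, 2.00, 2.00, 3.64), (0.17, 0.26, 0.26, 0.43)),
]


@dataclass(frozen=True)
class GroupSpec:
    cls: DiagnosisClass
    n: int
    means: Mapping[str, float]
    ses: Mapping[str, float]
    truncation: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(FACTOR_DOMAINS)
    )

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ContractError(f"group {self.cls.name}: n must be positive")
        for fid in FACTOR_IDS:
            if fid not in self.means or fid not in self.ses:
                raise ContractError(f"group {self.cls.name}: missing factor {fid}")
            if self.ses[fid] < 0:
                raise ContractError(f"group {self.cls.name}: negative SE for {fid}")
            lo, hi = self.truncation[fid]
            if not lo <= self.means[fid] <= hi:
                raise ContractError(
                    f"group {self.cls.name}: mean {self.means[fid]} for {fid} "
                    f"outside truncation bounds [{lo}, {hi}]"
                )
        object.__setattr__(self, "means", dict(self.means))
        object.__setattr__(self, "ses", dict(self.ses))
        object.__setattr__(self, "truncation", dict(self.truncation))


@dataclass(frozen=True)
class CohortSpec:
    groups: tuple[GroupSpec, ...]
    seed: int = 0
    distribution: str = "truncnorm"  # or "uniform"

    def __post_init__(self) -> None:
        classes = [g.cls for g in self.groups]
        if len(set(classes)) != len(classes):
            raise ContractError("group classes must be distinct")
        if self.distribution not in ("truncnorm", "uniform"):
            raise ContractError(f"unknown distribution {self.distribution!r}")
        object.__setattr__(self, "groups", tuple(self.groups))

    @property
    def total_n(self) -> int:
        return sum(g.n for g in self.groups)


def default_cohort_spec(seed: int = 0, distribution: str = "truncnorm") -> CohortSpec:
    """The study's four clinical groups: 90 + 25 + 25 + 25 = 165 patients."""
    groups = tuple(
        GroupSpec(
            cls=cls,
            n=n,
            means=dict(zip(FACTOR_IDS, means)),
            ses=dict(zip(FACTOR_IDS, ses)),
        )
        for cls, n, means, ses in _GROUP_TABLE
    )
    return CohortSpec(groups=groups, seed=seed, distribution=distribution)


def _calibrated_loc(mean: float, sd: float, lo: float, hi: float) -> float:
    """Location parameter whose [lo, hi]-truncated normal has mean ``mean``.

    The truncated mean is strictly increasing in the location and spans
    (lo, hi), so a unique root exists for any interior target mean.
    """

    def gap(loc: float) -> float:
        a, b = (lo - loc) / sd, (hi - loc) / sd
        return float(stats.truncnorm.mean(a, b, loc=loc, scale=sd)) - mean

    span = max(hi - lo, sd)
    left, right = mean - span, mean + span
    for _ in range(60):
        if gap(left) < 0:
            break
        left -= span
    for _ in range(60):
        if gap(right) > 0:
            break
        right += span
    if not (gap(left) < 0 < gap(right)):
        raise GenerationError(
            f"cannot place truncated-normal mean {mean} inside [{lo}, {hi}]"
        )
    return float(optimize.brentq(gap, left, right, xtol=1e-10))


def generate_synthetic_cohort(
    spec: CohortSpec,
) -> list[tuple[PatientRecord, DiagnosisClass]]:
    """Draw one cohort; deterministic for a given spec (seed included)."""
    rng = np.random.default_rng(spec.seed)
    out: list[tuple[PatientRecord, DiagnosisClass]] = []
    for group in spec.groups:
        columns: dict[str, np.ndarray] = {}
        for fid in FACTOR_IDS:
            lo, hi = group.truncation[fid]
            mean = group.means[fid]
            sd = group.ses[fid] * np.sqrt(group.n)
            if sd == 0.0:
                if not lo <= mean <= hi:
                    raise GenerationError(
                        f"group {group.cls.name}, {fid}: constant value {mean} "
                        f"outside [{lo}, {hi}]"
                    )
                columns[fid] = np.full(group.n, mean)
            elif spec.distribution == "uniform":
                columns[fid] = rng.uniform(lo, hi, size=group.n)
            else:
                loc = _calibrated_loc(mean, sd, lo, hi)
                a, b = (lo - loc) / sd, (hi - loc) / sd
                columns[fid] = stats.truncnorm.rvs(
                    a, b, loc=loc, scale=sd, size=group.n, random_state=rng
                )
        for i in range(group.n):
            record = PatientRecord(
                x={fid: float(columns[fid][i]) for fid in FACTOR_IDS},
                id=f"{group.cls.clinical_name}-{i + 1:03d}",
            )
            out.append((record, group.cls))
    return out


def fixture_patients() -> list[tuple[PatientRecord, DiagnosisClass]]:
    """The four group-mean factor vectors, labelled with their groups."""
    return [
        (
            PatientRecord(
                x=dict(zip(FACTOR_IDS, means)), id=cls.clinical_name
            ),
            cls,
        )
        for cls, _n, means, _ses in _GROUP_TABLE
    ]


# ---------------------------------------------------------------------------
# Descriptive cohort statistics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortTable:
    """Named subgroup counts against a total (e.g. males/females of a cohort)."""

    total: int
    counts: Mapping[str, int]

    def __post_init__(self) -> None:
        if self.total <= 0:
            raise ContractError("total must be positive")
        for name, k in self.counts.items():
            if k < 0:
                raise ContractError(f"count {name!r} is negative")
            if k > self.total:
                raise ContractError(f"count {name!r} ({k}) exceeds total {self.total}")
        object.__setattr__(self, "counts", dict(self.counts))


def percentage(k: float, n: float) -> float:
    """``100 k / n`` rounded to one decimal."""
    if n == 0:
        raise ContractError("zero denominator")
    return round(100.0 * k / n, 1)


def ratio(a: float, b: float) -> float:
    """``a / b`` rounded to one decimal."""
    if b == 0:
        raise ContractError("zero denominator")
    return round(a / b, 1)


def cohort_summary(table: CohortTable) -> dict[str, dict[str, float]]:
    """Per-subgroup counts and percentages of the table's total."""
    return {
        name: {"count": k, "percent": percentage(k, table.total)}
        for name, k in table.counts.items()
    }
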