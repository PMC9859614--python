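"""Core fuzzy-set machinery: membership functions, combiners, diagnostics.

Everything in this module is pure computation on plain values.  The
domain-specific content (which factors exist, which terms mean what for
coronary-artery grading) lives in :mod:`fuzzycad.knowledge_base`.

Membership functions come in two parametrisations:

* :class:`PiecewiseLinearMF` — spline-linear approximations of expert
  membership curves, given as half-open linear pieces ``[a; b)`` with the
  final piece closed.  This is the form the default knowledge base ships in.
* :class:`BellMF` — the generalised bell ``1 / (1 + ((x - b)/c)^2)`` with a
  peak coordinate ``b`` and a compression/extension parameter ``c``.  This is
  the form the tuning procedure optimises.

A degree of membership is always a number in ``[0, 1]``: raw piecewise-linear
values that fall slightly outside (an artifact of rounded published
coefficients) are clamped, never rejected.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence, Union


class DomainError(ValueError):
    """An input value lies outside the domain it is defined on."""


class ContractError(ValueError):
    """A call violates a documented precondition."""


class UndefinedCentroidError(ContractError):
    """Centre-of-gravity defuzzification of an all-zero fuzzy set."""


class TermLabel(enum.IntEnum):
    """The five linguistic terms, totally ordered low-to-high.

    L — low, LA — lower than average, A — average, HA — higher than
    average, H — high.
    """

    L = 0
    LA = 1
    A = 2
    HA = 3
    H = 4

    @classmethod
    def from_string(cls, s: str) -> "TermLabel":
        try:
            return cls[s]
        except KeyError:
            raise ContractError(
                f"unknown term label {s!r}; expected one of "
                f"{[t.name for t in cls]}"
            ) from None


def _clamp01(v: float) -> float:
    return 0.0 if v < 0.0 else (1.0 if v > 1.0 else v)


@dataclass(frozen=True)
class LinearSegment:
    """One linear piece ``slope * x + intercept`` on ``[lower, upper)``.

    ``upper_closed`` marks the final piece of a membership function, whose
    interval is closed on the right so the full domain is covered.
    """

    lower: float
    upper: float
    slope: float
    intercept: float
    upper_closed: bool = False

    def __post_init__(self) -> None:
        if not self.lower < self.upper:
            raise ContractError(
                f"segment requires lower < upper, got [{self.lower}, {self.upper}]"
            )

    def contains(self, x: float) -> bool:
        if self.upper_closed:
            return self.lower <= x <= self.upper
        return self.lower <= x < self.upper

    def raw(self, x: float) -> float:
        """Membership before clamping to [0, 1]."""
        return self.slope * x + self.intercept


@dataclass(frozen=True)
class PiecewiseLinearMF:
    """A membership function given as ordered, contiguous linear pieces.

    Segments are half-open ``[a; b)`` except the last, which is closed, so
    every point of the domain belongs to exactly one segment and the value at
    an interior breakpoint is taken from the segment on the right.
    """

    segments: tuple[LinearSegment, ...]
    domain: tuple[float, float]

    def __post_init__(self) -> None:
        segs = tuple(self.segments)
        object.__setattr__(self, "segments", segs)
        if not segs:
            raise ContractError("membership function needs at least one segment")
        xmin, xmax = self.domain
        if not xmin < xmax:
            raise ContractError(f"degenerate domain [{xmin}, {xmax}]")
        if not math.isclose(segs[0].lower, xmin) or not math.isclose(
            segs[-1].upper, xmax
        ):
            raise ContractError("segments do not span the domain")
        for left, right in zip(segs, segs[1:]):
            if not math.isclose(left.upper, right.lower):
                raise ContractError(
                    f"segments not contiguous at {left.upper} vs {right.lower}"
                )
        for seg in segs[:-1]:
            if seg.upper_closed:
                raise ContractError("only the final segment may be upper-closed")
        if not segs[-1].upper_closed:
            raise ContractError("the final segment must be upper-closed")

    def segment_at(self, x: float) -> LinearSegment:
        for seg in self.segments:
            if seg.contains(x):
                return seg
        raise DomainError(
            f"x={x} outside membership-function domain {list(self.domain)}"
        )

    def __call__(self, x: float) -> float:
        return _clamp01(self.segment_at(x).raw(x))

    @property
    def breakpoints(self) -> tuple[float, ...]:
        """Interior breakpoints (segment boundaries strictly inside the domain)."""
        return tuple(seg.upper for seg in self.segments[:-1])


@dataclass(frozen=True)
class BellMF:
    """Generalised bell membership ``1 / (1 + ((x - b) / c)^2)``.

    ``b`` is the coordinate of the maximum (where the degree equals 1) and
    ``c > 0`` controls compression/extension of the curve.
    """

    b: float
    c: float

    def __post_init__(self) -> None:
        if not self.c > 0:
            raise ContractError(f"bell spread c must be positive, got {self.c}")

    def __call__(self, x: float) -> float:
        z = (x - self.b) / self.c
        return 1.0 / (1.0 + z * z)


MembershipFunction = Union[PiecewiseLinearMF, BellMF]


@dataclass(frozen=True)
class LinguisticVariable:
    """A factor whose values are the five linguistic terms.

    Each term is formalised by a membership function over the variable's
    domain; exactly one function per :class:`TermLabel`.
    """

    factor_id: str
    description: str
    domain: tuple[float, float]
    terms: Mapping[TermLabel, MembershipFunction]

    def __post_init__(self) -> None:
        labels = set(self.terms)
        if labels != set(TermLabel):
            raise ContractError(
                f"variable {self.factor_id}: needs exactly the five terms "
                f"{[t.name for t in TermLabel]}, got {sorted(t.name for t in labels)}"
            )
        for label, mf in self.terms.items():
            if isinstance(mf, PiecewiseLinearMF) and not (
                math.isclose(mf.domain[0], self.domain[0])
                and math.isclose(mf.domain[1], self.domain[1])
            ):
                raise ContractError(
                    f"variable {self.factor_id}, term {label.name}: membership "
                    f"domain {mf.domain} differs from variable domain {self.domain}"
                )


@dataclass(frozen=True)
class CombinerConfig:
    """How rule antecedents and rule outputs are combined.

    The default min/max pair is the classical Mamdani reading (AND -> min,
    OR -> max); product/probabilistic-sum is the smooth alternative.
    """

    t_norm: str = "min"
    s_norm: str = "max"
    out_of_range: str = "error"  # or "clamp_to_domain"
    tie_break: str = "lowest_index"  # or "report_all"

    def __post_init__(self) -> None:
        if self.t_norm not in ("min", "product"):
            raise ContractError(f"unknown t-norm {self.t_norm!r}")
        if self.s_norm not in ("max", "prob_sum"):
            raise ContractError(f"unknown s-norm {self.s_norm!r}")
        if self.out_of_range not in ("error", "clamp_to_domain"):
            raise ContractError(f"unknown out_of_range policy {self.out_of_range!r}")
        if self.tie_break not in ("lowest_index", "report_all"):
            raise ContractError(f"unknown tie_break policy {self.tie_break!r}")


# ---------------------------------------------------------------------------
# Evaluation and combination
# ---------------------------------------------------------------------------

def evaluate_mf(
    mf: MembershipFunction,
    x: float,
    out_of_range: str = "error",
) -> float:
    """Degree of membership of ``x`` under ``mf``, always in [0, 1].

    Piecewise-linear functions have a bounded domain: outside it the call
    raises :class:`DomainError` unless ``out_of_range='clamp_to_domain'``, in
    which case ``x`` is clamped to the nearest domain endpoint first.  Bell
    functions are defined on the whole real line.
    """
    if not math.isfinite(x):
        raise ContractError(f"non-finite input x={x}")
    if isinstance(mf, BellMF):
        return mf(x)
    xmin, xmax = mf.domain
    if x < xmin or x > xmax:
        if out_of_range == "clamp_to_domain":
            x = xmin if x < xmin else xmax
        else:
            raise DomainError(f"x={x} outside domain [{xmin}, {xmax}]")
    return mf(x)


def _check_degrees(degrees: Sequence[float]) -> None:
    if len(degrees) == 0:
        raise ContractError("cannot combine an empty list of degrees")
    for d in degrees:
        if not (0.0 <= d <= 1.0):
            raise ContractError(f"degree {d} outside [0, 1]")


def combine_and(degrees: Sequence[float], t_norm: str = "min") -> float:
    """Fuzzy conjunction of degrees under the given t-norm."""
    _check_degrees(degrees)
    if t_norm == "min":
        return min(degrees)
    if t_norm == "product":
        return math.prod(degrees)
    raise ContractError(f"unknown t-norm {t_norm!r}")


def combine_or(degrees: Sequence[float], s_norm: str = "max") -> float:
    """Fuzzy disjunction of degrees under the given s-norm."""
    _check_degrees(degrees)
    if s_norm == "max":
        return max(degrees)
    if s_norm == "prob_sum":
        return 1.0 - math.prod(1.0 - d for d in degrees)
    raise ContractError(f"unknown s-norm {s_norm!r}")


def normalize_to_u(x: float, domain: tuple[float, float]) -> float:
    """Map ``x`` from its factor range onto the common universe U = [0, 4].

    ``u = 4 (x - xmin) / (xmax - xmin)``.
    """
    xmin, xmax = domain
    if not xmin < xmax:
        raise ContractError(f"degenerate domain [{xmin}, {xmax}]")
    return 4.0 * (x - xmin) / (xmax - xmin)


def denormalize_from_u(u: float, domain: tuple[float, float]) -> float:
    """Inverse of :func:`normalize_to_u`."""
    xmin, xmax = domain
    if not xmin < xmax:
        raise ContractError(f"degenerate domain [{xmin}, {xmax}]")
    return xmin + u * (xmax - xmin) / 4.0


def defuzzify_cog(universe: Sequence[float], degrees: Sequence[float]) -> float:
    """Centre-of-gravity defuzzification: the membership-weighted mean.

    Raises :class:`UndefinedCentroidError` if no degree is positive — an
    all-zero fuzzy set has no centroid and the ambiguity must surface.
    """
    if len(universe) != len(degrees) or len(universe) == 0:
        raise ContractError("universe and degrees must be equal-length, non-empty")
    _check_degrees(degrees)
    total = float(sum(degrees))
    if total == 0.0:
        raise UndefinedCentroidError("all membership degrees are zero")
    return float(sum(u * d for u, d in zip(universe, degrees)) / total)


# ---------------------------------------------------------------------------
# Consistency diagnostics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BreakpointJump:
    term: TermLabel
    x: float
    jump: float
    flagged: bool


@dataclass(frozen=True)
class TermPeak:
    term: TermLabel
    x: float
    value: float


@dataclass(frozen=True)
class ConsistencyReport:
    """Numerical quality report for one linguistic variable.

    ``jumps``    post-clamp discontinuities at interior breakpoints
                 (rounded published coefficients make left and right pieces
                 disagree slightly; large jumps are flagged);
    ``coverage`` min over a grid of the max-over-terms degree — how well the
                 five terms jointly cover the domain;
    ``peaks``    each term's maximal degree and its location.
    """

    factor_id: str
    jumps: tuple[BreakpointJump, ...]
    coverage: float
    peaks: tuple[TermPeak, ...]

    @property
    def flagged_jumps(self) -> tuple[BreakpointJump, ...]:
        return tuple(j for j in self.jumps if j.flagged)

    def to_dict(self) -> dict:
        return {
            "factor_id": self.factor_id,
            "coverage": self.coverage,
            "jumps": [
                {
                    "term": j.term.name,
                    "x": j.x,
                    "jump": j.jump,
                    "flagged": j.flagged,
                }
                for j in self.jumps
            ],
            "peaks": [
                {"term": p.term.name, "x": p.x, "value": p.value}
                for p in self.peaks
            ],
        }


def _grid(domain: tuple[float, float], step: float) -> list[float]:
    xmin, xmax = domain
    n = max(1, int(round((xmax - xmin) / step)))
    return [xmin + (xmax - xmin) * i / n for i in range(n + 1)]


def check_variable_consistency(
    var: LinguisticVariable,
    grid_step: float = 1e-3,
    jump_tol: float = 0.05,
) -> ConsistencyReport:
    """Grid-based diagnostics for a linguistic variable.

    Continuity is a diagnostic here, not an invariant: the published
    piecewise coefficients are rounded and do not always agree where two
    pieces meet, so jumps are reported (and flagged beyond ``jump_tol``)
    rather than treated as errors.
    """
    grid = _grid(var.domain, grid_step)

    jumps: list[BreakpointJump] = []
    for label in TermLabel:
        mf = var.terms[label]
        if not isinstance(mf, PiecewiseLinearMF):
            continue  # bell functions are continuous by construction
        for i, bp in enumerate(mf.breakpoints):
            left = _clamp01(mf.segments[i].raw(bp))
            right = _clamp01(mf.segments[i + 1].raw(bp))
            jump = abs(right - left)
            jumps.append(
                BreakpointJump(term=label, x=bp, jump=jump, flagged=jump > jump_tol)
            )

    coverage = min(
        max(evaluate_mf(var.terms[label], x) for label in TermLabel) for x in grid
    )

    peaks = []
    for label in TermLabel:
        mf = var.terms[label]
        best_x, best_v = max(
            ((x, evaluate_mf(mf, x)) for x in grid), key=lambda t: t[1]
        )
        peaks.append(TermPeak(term=label, x=best_x, value=best_v))

    return ConsistencyReport(
        factor_id=var.factor_id,
        jumps=tuple(jumps),
        coverage=float(coverage),
        peaks=tuple(peaks),
    )
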