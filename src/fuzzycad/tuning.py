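"""Least-squares tuning of membership parameters and rule weights.

The tunable model is the rule base with every term in bell form
``mu(x) = 1 / (1 + ((x - b)/c)^2)``: one peak coordinate ``b`` and one
spread ``c`` per (factor, term) pair that some rule actually references,
plus one weight ``w`` per rule.  The objective is the sum over training
examples and classes of the squared difference between the model's class
membership and the target membership (class labels become one-hot targets).

Terms no rule references do not enter the inference function at all, so
their parameters are unidentifiable and are excluded from the flattened
parameter vector.

The update rule is standard bounded numerical optimization (derivative-free
Nelder-Mead by default, with L-BFGS-B and a seeded random-restart search as
alternatives); all of them only ever accept parameter vectors that do not
increase the objective, so the accepted-iterate trajectory is
non-increasing by construction.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence, Union

import numpy as np
from scipy import optimize

from .fuzzy_core import (
    BellMF,
    CombinerConfig,
    ContractError,
    PiecewiseLinearMF,
    TermLabel,
    evaluate_mf,
)
from .knowledge_base import (
    FACTOR_IDS,
    DiagnosisClass,
    KnowledgeBase,
    LinguisticVariable,
    Rule,
)

logger = logging.getLogger(__name__)

_CLASSES = tuple(DiagnosisClass)


@dataclass(frozen=True)
class TrainingExample:
    """One supervised observation: factor values and a target.

    ``y`` is either a :class:`DiagnosisClass` label (converted to a one-hot
    membership target) or an explicit 4-vector of target class memberships.
    """

    x: tuple[float, float, float, float]
    y: Union[DiagnosisClass, tuple[float, float, float, float]]

    def target(self) -> np.ndarray:
        if isinstance(self.y, DiagnosisClass):
            t = np.zeros(4)
            t[self.y - 1] = 1.0
            return t
        t = np.asarray(self.y, dtype=float)
        if t.shape != (4,) or not ((t >= 0.0) & (t <= 1.0)).all():
            raise ContractError(f"membership target {self.y!r} invalid")
        return t


@dataclass(frozen=True)
class TuningConfig:
    what: frozenset = frozenset({"b", "c", "w"})
    optimizer: str = "nelder_mead"
    max_iter: int = 500
    tol: float = 1e-10
    seed: int = 0
    combiners: CombinerConfig = CombinerConfig(t_norm="min", s_norm="max")
    c_min: float | None = None  # default: 1% of each factor's domain width
    c_max: float | None = None  # default: 2x each factor's domain width

    def __post_init__(self) -> None:
        what = frozenset(self.what)
        object.__setattr__(self, "what", what)
        if not what or not what <= {"b", "c", "w"}:
            raise ContractError(f"tunable subset {set(self.what)} invalid")
        if self.optimizer not in ("nelder_mead", "lbfgsb", "random_restart"):
            raise ContractError(f"unknown optimizer {self.optimizer!r}")
        if self.c_min is not None and self.c_min <= 0:
            raise ContractError("c_min must be positive")
        if self.max_iter < 0:
            raise ContractError("max_iter must be non-negative")


@dataclass(frozen=True)
class TuningResult:
    tuned_kb: KnowledgeBase
    objective_trajectory: tuple[float, ...]
    initial_objective: float
    final_objective: float
    recovered_params: Mapping[str, float]


# ---------------------------------------------------------------------------
# Piecewise-linear -> bell conversion
# ---------------------------------------------------------------------------

def pl_to_bell(kb: KnowledgeBase, grid_n: int = 4001) -> KnowledgeBase:
    """Convert every piecewise-linear term to an equivalent-shape bell.

    ``b`` is placed at the term's grid argmax; ``c`` is half the x-distance
    between the two half-maximum (degree 0.5) crossings, each side falling
    back to the distance from the peak to the domain edge when the degree
    never drops below 0.5 on that side.  The conversion is logged per term.
    """
    variables = {}
    for fid, var in kb.variables.items():
        xmin, xmax = var.domain
        xs = np.linspace(xmin, xmax, grid_n)
        terms: dict[TermLabel, BellMF] = {}
        for label, mf in var.terms.items():
            if isinstance(mf, BellMF):
                terms[label] = mf
                continue
            ys = np.array([mf(x) for x in xs])
            k = int(np.argmax(ys))
            b = float(xs[k])
            below_left = np.nonzero(ys[:k] < 0.5)[0]
            left = float(xs[below_left[-1]]) if below_left.size else xmin
            below_right = np.nonzero(ys[k:] < 0.5)[0]
            right = float(xs[k + below_right[0]]) if below_right.size else xmax
            half_left = max(b - left, 1e-6)
            half_right = max(right - b, 1e-6)
            c = 0.5 * (half_left + half_right)
            terms[label] = BellMF(b=b, c=c)
            logger.info(
                "converted %s.%s to bell form: b=%.4f c=%.4f", fid, label.name, b, c
            )
        variables[fid] = LinguisticVariable(
            factor_id=fid,
            description=var.description,
            domain=var.domain,
            terms=terms,
        )
    return KnowledgeBase(
        variables=variables, rules=kb.rules, metadata=kb.metadata
    )


def _is_bell_kb(kb: KnowledgeBase) -> bool:
    return all(
        isinstance(mf, BellMF)
        for var in kb.variables.values()
        for mf in var.terms.values()
    )


# ---------------------------------------------------------------------------
# Parameter flattening
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ParamLayout:
    """Maps a flat parameter vector onto (b, c, w) entries with bounds."""

    names: tuple[str, ...]
    bounds: tuple[tuple[float, float], ...]
    entries: tuple[tuple, ...]  # ("b"|"c", fid, TermLabel) or ("w", rule_idx)

    @property
    def n(self) -> int:
        return len(self.names)


def build_layout(kb: KnowledgeBase, config: TuningConfig) -> ParamLayout:
    names: list[str] = []
    bounds: list[tuple[float, float]] = []
    entries: list[tuple] = []
    referenced = kb.referenced_terms()
    for fid in FACTOR_IDS:
        var = kb.variables[fid]
        width = var.domain[1] - var.domain[0]
        c_lo = config.c_min if config.c_min is not None else 0.01 * width
        c_hi = config.c_max if config.c_max is not None else 2.0 * width
        for label in TermLabel:
            if (fid, label) not in referenced:
                continue
            if "b" in config.what:
                names.append(f"b[{fid}.{label.name}]")
                bounds.append(var.domain)
                entries.append(("b", fid, label))
            if "c" in config.what:
                names.append(f"c[{fid}.{label.name}]")
                bounds.append((c_lo, c_hi))
                entries.append(("c", fid, label))
    if "w" in config.what:
        for i in range(len(kb.rules)):
            names.append(f"w[{i}]")
            bounds.append((0.0, 1.0))
            entries.append(("w", i))
    return ParamLayout(names=tuple(names), bounds=tuple(bounds), entries=tuple(entries))


def flatten_params(kb: KnowledgeBase, layout: ParamLayout) -> np.ndarray:
    out = np.empty(layout.n)
    for i, entry in enumerate(layout.entries):
        if entry[0] == "w":
            out[i] = kb.rules[entry[1]].weight
        else:
            mf = kb.variables[entry[1]].terms[entry[2]]
            if not isinstance(mf, BellMF):
                raise ContractError(
                    f"term {entry[1]}.{entry[2].name} is not in bell form; "
                    "convert with pl_to_bell first"
                )
            out[i] = mf.b if entry[0] == "b" else mf.c
    return out


def apply_params(
    kb: KnowledgeBase, layout: ParamLayout, params: np.ndarray
) -> KnowledgeBase:
    params = np.asarray(params, dtype=float)
    if params.shape != (layout.n,):
        raise ContractError(
            f"parameter vector length {params.shape} does not match layout ({layout.n},)"
        )
    new_terms: dict[tuple[str, TermLabel], dict[str, float]] = {}
    new_weights: dict[int, float] = {}
    for entry, value in zip(layout.entries, params):
        if entry[0] == "w":
            new_weights[entry[1]] = float(value)
        else:
            new_terms.setdefault((entry[1], entry[2]), {})[entry[0]] = float(value)

    variables = {}
    for fid, var in kb.variables.items():
        terms = {}
        for label, mf in var.terms.items():
            upd = new_terms.get((fid, label))
            if upd is None:
                terms[label] = mf
            else:
                if not isinstance(mf, BellMF):
                    raise ContractError(
                        f"term {fid}.{label.name} is not in bell form"
                    )
                terms[label] = BellMF(
                    b=upd.get("b", mf.b), c=upd.get("c", mf.c)
                )
        variables[fid] = LinguisticVariable(
            factor_id=fid,
            description=var.description,
            domain=var.domain,
            terms=terms,
        )
    rules = tuple(
        replace(rule, weight=new_weights.get(i, rule.weight))
        for i, rule in enumerate(kb.rules)
    )
    return KnowledgeBase(variables=variables, rules=rules, metadata=kb.metadata)


# ---------------------------------------------------------------------------
# Vectorized forward pass and the objective
# ---------------------------------------------------------------------------

def _rule_arrays(kb: KnowledgeBase) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per-rule bell parameters: B, C (n_rules x 4), weights, class indices."""
    n = len(kb.rules)
    B = np.empty((n, 4))
    C = np.empty((n, 4))
    W = np.empty(n)
    K = np.empty(n, dtype=int)
    for i, rule in enumerate(kb.rules):
        for j, fid in enumerate(FACTOR_IDS):
            mf = kb.variables[fid].terms[rule.antecedent[fid]]
            if not isinstance(mf, BellMF):
                raise ContractError("vectorized pass requires a bell-form KB")
            B[i, j] = mf.b
            C[i, j] = mf.c
        W[i] = rule.weight
        K[i] = rule.consequent - 1
    return B, C, W, K


def bell_class_membership_matrix(
    X: np.ndarray, kb: KnowledgeBase, config: CombinerConfig = CombinerConfig()
) -> np.ndarray:
    """Class memberships for a batch of patients under a bell-form KB.

    ``X`` is (n_patients, 4); the result is (n_patients, 4) in class order
    I..IV.  Must agree exactly with the scalar engine in
    :mod:`fuzzycad.inference`; a test holds the two paths together.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    B, C, W, K = _rule_arrays(kb)
    Z = (X[:, None, :] - B[None, :, :]) / C[None, :, :]
    D = 1.0 / (1.0 + Z * Z)  # (n, n_rules, 4)
    if config.t_norm == "min":
        act = D.min(axis=2)
    else:
        act = D.prod(axis=2)
    act = act * W[None, :]
    out = np.zeros((X.shape[0], 4))
    for cls_idx in range(4):
        cols = act[:, K == cls_idx]
        if cols.shape[1] == 0:
            raise ContractError(f"class index {cls_idx + 1} has no rules")
        if config.s_norm == "max":
            out[:, cls_idx] = cols.max(axis=1)
        else:
            out[:, cls_idx] = 1.0 - (1.0 - cols).prod(axis=1)
    return out


def tuning_objective(
    params: np.ndarray,
    training: Sequence[TrainingExample],
    kb_template: KnowledgeBase,
    config: TuningConfig,
    layout: ParamLayout | None = None,
) -> float:
    """Sum of squared divergences between model and target memberships."""
    if len(training) == 0:
        raise ContractError("empty training set")
    layout = layout if layout is not None else build_layout(kb_template, config)
    kb = apply_params(kb_template, layout, np.asarray(params, dtype=float))
    X = np.array([ex.x for ex in training], dtype=float)
    Y = np.array([ex.target() for ex in training])
    pred = bell_class_membership_matrix(X, kb, config.combiners)
    return float(((pred - Y) ** 2).sum())


# ---------------------------------------------------------------------------
# The tuner
# ---------------------------------------------------------------------------

class _BestTracker:
    """Wraps the objective; remembers the best (lowest) evaluation seen."""

    def __init__(self, fun):
        self.fun = fun
        self.best_f = math.inf
        self.best_x: np.ndarray | None = None
        self.trajectory: list[float] = []

    def __call__(self, x: np.ndarray) -> float:
        f = self.fun(x)
        if f < self.best_f:
            self.best_f = f
            self.best_x = np.array(x, dtype=float)
        return f

    def accept(self) -> None:
        """Record the current best as an accepted iterate."""
        if not self.trajectory or self.best_f <= self.trajectory[-1]:
            self.trajectory.append(self.best_f)


def tune(
    kb: KnowledgeBase,
    training: Sequence[TrainingExample],
    config: TuningConfig = TuningConfig(),
) -> TuningResult:
    """Fit the selected parameters to training data by least squares.

    Piecewise-linear knowledge bases are first converted to bell form (see
    :func:`pl_to_bell`).  The returned parameters always respect their
    bounds, the accepted-iterate trajectory is non-increasing, the final
    objective never exceeds the initial one, and identical config + seed
    reproduce the result exactly.
    """
    if len(training) == 0:
        raise ContractError("empty training set")
    if not _is_bell_kb(kb):
        kb = pl_to_bell(kb)
    layout = build_layout(kb, config)
    x0 = flatten_params(kb, layout)
    lo = np.array([b[0] for b in layout.bounds])
    hi = np.array([b[1] for b in layout.bounds])
    if (lo > hi).any():
        raise ContractError("infeasible bounds")
    x0 = np.clip(x0, lo, hi)

    X = np.array([ex.x for ex in training], dtype=float)
    Y = np.array([ex.target() for ex in training])

    def objective(p: np.ndarray) -> float:
        pred = bell_class_membership_matrix(
            X, apply_params(kb, layout, p), config.combiners
        )
        return float(((pred - Y) ** 2).sum())

    tracker = _BestTracker(objective)
    f0 = tracker(x0)
    tracker.accept()

    if config.max_iter > 0:
        if config.optimizer == "nelder_mead":
            optimize.minimize(
                tracker,
                x0,
                method="Nelder-Mead",
                bounds=optimize.Bounds(lo, hi),
                options={
                    "maxiter": config.max_iter,
                    "fatol": config.tol,
                    "xatol": 1e-8,
                    "adaptive": True,
                },
                callback=lambda xk: tracker.accept(),
            )
        elif config.optimizer == "lbfgsb":
            optimize.minimize(
                tracker,
                x0,
                method="L-BFGS-B",
                bounds=list(zip(lo, hi)),
                options={"maxiter": config.max_iter, "ftol": config.tol},
                callback=lambda xk: tracker.accept(),
            )
        else:  # random_restart
            rng = np.random.default_rng(config.seed)
            span = hi - lo
            for it in range(config.max_iter):
                sigma = 0.25 * (1.0 - it / config.max_iter) + 0.01
                if it % 50 == 49:
                    candidate = rng.uniform(lo, hi)
                else:
                    base = tracker.best_x if tracker.best_x is not None else x0
                    candidate = np.clip(
                        base + rng.normal(0.0, sigma * span), lo, hi
                    )
                tracker(candidate)
                tracker.accept()

    best_x = tracker.best_x if tracker.best_x is not None else x0
    best_x = np.clip(best_x, lo, hi)
    tuned_kb = apply_params(kb, layout, best_x)
    return TuningResult(
        tuned_kb=tuned_kb,
        objective_trajectory=tuple(tracker.trajectory),
        initial_objective=f0,
        final_objective=tracker.best_f,
        recovered_params={
            name: float(v) for name, v in zip(layout.names, best_x)
        },
    )
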