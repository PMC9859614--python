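# Methods

## Model

The system is a Mamdani-style fuzzy classifier over four anatomical
lesion factors X1–X4 (unitless severity scores; their empirical ranges are
the variable domains). Each factor is a linguistic variable with five
terms L < LA < A < HA < H, each term a membership function over the
factor's domain. A rule is a complete antecedent (one term per factor), a
consequent class among I (NSTEMI), II (UAP), III (STEMI), IV (StAP), and a
weight in [0, 1]. Inference per patient:

1. fuzzify: evaluate all 4 × 5 term memberships at the patient's values;
2. activate: each rule's activation is its weight times the t-norm (min by
   default, product optionally) of its four antecedent degrees;
3. compose: each class membership is the s-norm (max by default,
   probabilistic sum optionally) of its rules' activations;
4. decide: the class of maximal membership. Ties go to the lowest class
   index and are flagged; memberships are compared at full floating
   precision, with rounding applied only at output time (6 significant
   digits in the CLI).

With unit weights and min/max combiners this reproduces the published
union-of-conjunctions expressions for the four classes exactly;
`closed_form_class_membership` hand-codes those expressions (three
conjunctions for class I, four for II, three for III, four for IV) and
acts as an independent oracle for the generic engine in the test suite.

The canonical rule list is the published fourteen-row table. The printed
class-III closed-form expression repeats its first conjunction verbatim
where the table's first class-III row ends in HA; the table is taken as
canonical and the expression treated as carrying a typographical slip, so
class III has three distinct antecedents, all requiring X3 = HA.

## Membership functions

The default knowledge base ships the twenty published piecewise-linear
terms verbatim. Conventions for the printed "[a; b)" pieces:

* half-open segments, the last closed: at an interior breakpoint the
  right-hand segment wins, so evaluation is single-valued everywhere;
* raw linear values slightly outside [0, 1] — an artifact of the rounded
  printed coefficients (e.g. μ_H(X1) at the domain's lower edge evaluates
  to −0.0107) — are clamped, not rejected;
* continuity is a *diagnostic*, not an invariant.
  `check_variable_consistency` reports every post-clamp breakpoint jump
  (the rounded coefficients leave, e.g., a 0.103 post-clamp disagreement
  in X2's term A at x = 2.3, about 0.2 before clamping), the per-factor
  coverage min-over-grid of max-over-terms (≈ 0.74 for all four factors on
  a 10⁻³ grid), and each term's peak (all ≥ 0.95). The functions are
  shipped as printed rather than smoothed: fidelity over aesthetics.
* term degrees are not renormalised to sum to 1 across the five terms.

Out-of-range inputs raise by default (the domains are empirical min/max
over the study cohort, so silent extrapolation is unsafe); a
`clamp_to_domain` policy is available for screening use. The common
universe mapping u = 4(x − x̲)/(x̄ − x̲) onto U = [0, 4] and
centre-of-gravity defuzzification Σuμ/Σμ are provided as utilities; an
all-zero fuzzy set has no centroid and raises rather than returning a
default.

## Tuning

Tuning operates on the bell parametrisation μ(x) = 1/(1 + ((x − b)/c)²):
b is the peak coordinate, c > 0 the compression/extension spread. A
piecewise-linear knowledge base is converted explicitly (and logged):
b is the term's grid argmax, c half the x-distance between the two
half-maximum crossings, each side falling back to the distance from peak
to domain edge when the degree never drops below 0.5 on that side
(4001-point grid).

The objective is the sum over training examples and classes of the
squared difference between model class membership and target; class
labels become one-hot membership targets, explicit 4-vector targets are
accepted as-is. The flattened parameter vector holds one (b, c) per
(factor, term) pair referenced by at least one rule — terms no rule uses
(X1·H, X2·H, X3·H, X4·L under the canonical rules) do not enter the
inference function, so their parameters are unidentifiable and excluded —
plus one weight per rule. Bounds: b within the factor domain, c in
[1% , 200%] of the domain width by default (overridable), w in [0, 1].

No closed-form update rule is assumed: optimization is standard bounded
numerical search — derivative-free Nelder-Mead by default, L-BFGS-B with
numerical gradients, or a seeded annealed random-restart search. All
three track the best parameter vector ever evaluated, so the
accepted-iterate trajectory is non-increasing and the final objective
never exceeds the initial one; identical config and seed reproduce the
result bit-for-bit. A vectorised forward pass evaluates batches of
patients under a bell-form knowledge base; a test pins it to the scalar
engine at 1e-14.

The recovery experiment (noise-free targets generated from the model
itself, peaks perturbed ±10%, 200 examples) is run with the smooth
product / probabilistic-sum combiners: under min/max the objective is
piecewise-flat in b (a parameter only matters where its rule attains the
min/max), which makes the experiment ill-posed for derivative-free and
gradient methods alike. With the smooth combiners both L-BFGS-B and
Nelder-Mead recover every peak to well under 0.1% with final objectives
below 1e-10.

## Synthetic cohorts

The generator emulates the study cohort: four groups of 90 (NSTEMI),
25 (UAP), 25 (STEMI) and 25 (StAP) patients, each factor summarised as
mean ± SEM and truncated to the factor's empirical range. Choices:

* the printed ± is read as the standard error of the mean, so the
  per-record standard deviation is sd = se·√n (conventional for such
  tables, but stated here because the source never defines the ±);
* the distribution family is a truncated normal (a uniform alternative is
  available); the family is the package's choice — only mean, SEM and
  range are given;
* truncation pulls the mean of a normal toward the centre of the window
  (for the NSTEMI group's X1, naively centring the normal at 2.57 on
  [1.83, 2.76] with sd ≈ 0.66 biases the realized mean by ≈ 0.25), so the
  location parameter is calibrated by root finding until the truncated
  distribution's mean equals the printed group mean; the scale stays
  se·√n, so the realized spread is somewhat below sd — means are matched
  exactly in expectation, variances are not;
* the UAP group's X3 is printed as 1.00 ± 0 and is generated as the
  constant 1.00;
* generated labels are the generating group. They are *not* a claim that
  the fuzzy engine reproduces them: on default cohorts the engine agrees
  with the generating labels for roughly a third of records (the group
  mean profiles overlap heavily within the narrow factor ranges), and the
  package reports agreement rather than asserting it. Passing tests
  therefore demonstrate the engine's internal correctness and the
  generator's statistical fidelity to the published summary table — not
  clinical accuracy on real angiographic data, which the published 95%
  expert-agreement figure refers to and which cannot be reproduced
  without the original cohort.

Descriptive-statistics helpers (percentage to one decimal, ratio to one
decimal) reproduce the study's printed cohort counts exactly and refuse
zero denominators.

## Problem sizes and numerical choices

The test suite and the acceptance script use 1000 random patients for the
oracle-equivalence check, 10⁴-point grids per factor for membership
sweeps, 200 training examples for recovery experiments and 20 seeds for
stochastic-mean checks; each completes in seconds on one CPU. Degenerate
inputs fail loudly: empty degree lists, empty cohorts, empty training
sets, non-finite memberships and zero denominators all raise typed
errors. When no rule fires at all (every class membership zero) batch
classification defaults to class I with a tie flag and a logged warning
so cohort runs complete; this is configurable to raise instead.

## Known limitations

* The shipped membership functions are exactly the rounded published
  coefficients; their small breakpoint discontinuities are reported, not
  repaired.
* The piecewise-linear → bell conversion preserves peak location and
  half-maximum width, not the full curve shape; tuned and untuned models
  are therefore not interchangeable point-for-point.
* The engine's decision set is the four clinical forms; no severity
  ordering beyond the class indices is imposed, and memberships are not
  calibrated probabilities.
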