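"""Membership evaluation, combiners, normalization, defuzzification."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fuzzycad import (
    BellMF,
    CombinerConfig,
    ContractError,
    DomainError,
    LinearSegment,
    PiecewiseLinearMF,
    TermLabel,
    UndefinedCentroidError,
    check_variable_consistency,
    combine_and,
    combine_or,
    defuzzify_cog,
    denormalize_from_u,
    evaluate_mf,
    normalize_to_u,
)
from fuzzycad.knowledge_base import FACTOR_DOMAINS


def triangle(domain, peak):
    """Exact triangular membership for continuity checks."""
    lo, hi = domain
    return PiecewiseLinearMF(
        segments=(
            LinearSegment(lo, peak, 1 / (peak - lo), -lo / (peak - lo)),
            LinearSegment(peak, hi, -1 / (hi - peak), hi / (hi - peak), True),
        ),
        domain=domain,
    )


class TestEvaluateMF:
    @pytest.mark.parametrize(
        "fid,term,x,expected",
        [
            # published pieces substituted by hand: 2.47 - 1.47*1.0 clamps to 1
            ("X3", TermLabel.L, 1.0, 1.00),
            # 0.71*1.83 - 1.31 = -0.0107, clamped to 0
            ("X1", TermLabel.H, 1.83, 0.00),
            # 1.56*2.5 - 3.2 = 0.7 on the middle piece
            ("X2", TermLabel.HA, 2.50, 0.70),
            # 0.769*2.5 - 1.09 = 0.8325
            ("X4", TermLabel.LA, 2.50, 0.8325),
        ],
    )
    def test_published_formula_values(self, kb, fid, term, x, expected):
        assert evaluate_mf(kb.variables[fid].terms[term], x) == pytest.approx(
            expected, abs=1e-12
        )

    def test_out_of_domain_errors_by_default(self, kb):
        with pytest.raises(DomainError):
            evaluate_mf(kb.variables["X1"].terms[TermLabel.L], 3.5)

    def test_out_of_domain_clamps_under_policy(self, kb):
        mf = kb.variables["X1"].terms[TermLabel.L]
        assert evaluate_mf(mf, 3.5, "clamp_to_domain") == evaluate_mf(mf, 2.76)

    def test_bell_peak_and_symmetry(self):
        mf = BellMF(b=2.0, c=0.5)
        assert evaluate_mf(mf, 2.0) == 1.0
        assert evaluate_mf(mf, 1.5) == pytest.approx(0.5)
        assert evaluate_mf(mf, 2.5) == pytest.approx(0.5)

    def test_bell_requires_positive_spread(self):
        with pytest.raises(ContractError):
            BellMF(b=0.0, c=0.0)

    @given(st.floats(min_value=1.83, max_value=2.76))
    @settings(max_examples=200, deadline=None)
    def test_degrees_always_in_unit_interval(self, x):
        from fuzzycad import build_default_knowledge_base

        var = build_default_knowledge_base().variables["X1"]
        for label in TermLabel:
            assert 0.0 <= evaluate_mf(var.terms[label], x) <= 1.0

    def test_segment_selection_is_total_and_unambiguous(self, kb):
        # every grid point of every factor falls in exactly one segment
        for fid, var in kb.variables.items():
            lo, hi = var.domain
            for label in TermLabel:
                mf = var.terms[label]
                for i in range(10_000):
                    x = lo + (hi - lo) * i / 9_999
                    hits = [s for s in mf.segments if s.contains(x)]
                    assert len(hits) == 1, (fid, label, x)

    def test_breakpoint_taken_from_right_segment(self, kb):
        # half-open [a;b): at x=2.06 the L term of X1 uses 1.97 - 0.71x
        mf = kb.variables["X1"].terms[TermLabel.L]
        assert evaluate_mf(mf, 2.06) == pytest.approx(1.97 - 0.71 * 2.06)


class TestCombiners:
    def test_and_min_of_listed_values(self):
        assert combine_and([0.818, 0.7, 1.0, 0.8325], "min") == 0.7

    def test_and_product(self):
        assert combine_and([0.5, 0.5], "product") == pytest.approx(0.25)

    @given(st.floats(min_value=0, max_value=1))
    @settings(max_examples=50, deadline=None)
    def test_singleton_identity(self, d):
        assert combine_and([d], "min") == d
        assert combine_and([d], "product") == d
        assert combine_or([d], "max") == d
        assert combine_or([d], "prob_sum") == pytest.approx(d)

    def test_or_zero_case(self):
        assert combine_or([0, 0, 0], "max") == 0

    def test_prob_sum(self):
        assert combine_or([0.5, 0.5], "prob_sum") == pytest.approx(0.75)

    @pytest.mark.parametrize("fn", [combine_and, combine_or])
    def test_empty_list_rejected(self, fn):
        with pytest.raises(ContractError):
            fn([])

    @pytest.mark.parametrize("fn", [combine_and, combine_or])
    def test_out_of_unit_degree_rejected(self, fn):
        with pytest.raises(ContractError):
            fn([0.5, 1.2])


class TestNormalization:
    @pytest.mark.parametrize(
        "x,expected", [(1.83, 0.0), (2.76, 4.0), (2.295, 2.0)]
    )
    def test_x1_boundaries_and_midpoint(self, x, expected):
        assert normalize_to_u(x, FACTOR_DOMAINS["X1"]) == pytest.approx(expected)

    @given(st.floats(min_value=2.07, max_value=4.67))
    @settings(max_examples=200, deadline=None)
    def test_round_trip_identity(self, x):
        dom = FACTOR_DOMAINS["X4"]
        assert denormalize_from_u(normalize_to_u(x, dom), dom) == pytest.approx(
            x, abs=1e-12
        )

    def test_degenerate_domain_rejected(self):
        with pytest.raises(ContractError):
            normalize_to_u(1.0, (2.0, 2.0))


class TestDefuzzify:
    @pytest.mark.parametrize(
        "universe,degrees,expected",
        [
            ([0, 1, 2], [0, 1, 0], 1.0),
            ([0, 2], [0.5, 0.5], 1.0),
            ([0, 1, 2, 3], [0.2, 0.4, 0.4, 0.2], 1.5),
        ],
    )
    def test_centroid(self, universe, degrees, expected):
        assert defuzzify_cog(universe, degrees) == pytest.approx(expected)

    def test_all_zero_degrees_signal(self):
        with pytest.raises(UndefinedCentroidError):
            defuzzify_cog([0, 1], [0, 0])

    @given(st.floats(min_value=-10, max_value=10))
    @settings(max_examples=50, deadline=None)
    def test_translation_equivariance(self, delta):
        universe = [0.0, 1.0, 2.0, 3.0]
        degrees = [0.1, 0.9, 0.4, 0.2]
        base = defuzzify_cog(universe, degrees)
        shifted = defuzzify_cog([u + delta for u in universe], degrees)
        assert shifted == pytest.approx(base + delta, abs=1e-9)

    def test_result_within_universe(self):
        v = defuzzify_cog([1, 2, 3], [0.2, 0.3, 0.1])
        assert 1 <= v <= 3


class TestConsistencyReport:
    def test_default_x1_peaks_near_one(self, kb):
        rep = check_variable_consistency(kb.variables["X1"])
        assert all(p.value >= 0.95 for p in rep.peaks)

    def test_x2_term_a_breakpoint_flagged(self, kb):
        # rising piece 1.59x-2.76 and falling piece 4.76-1.59x disagree at 2.3
        rep = check_variable_consistency(kb.variables["X2"], jump_tol=0.05)
        flagged = [(j.term, j.x) for j in rep.flagged_jumps]
        assert (TermLabel.A, 2.3) in flagged

    def test_exact_triangles_report_zero_jumps(self):
        from fuzzycad import LinguisticVariable

        dom = (0.0, 4.0)
        var = LinguisticVariable(
            factor_id="T",
            description="synthetic triangular variable",
            domain=dom,
            terms={
                TermLabel.L: triangle(dom, 0.5),
                TermLabel.LA: triangle(dom, 1.0),
                TermLabel.A: triangle(dom, 2.0),
                TermLabel.HA: triangle(dom, 3.0),
                TermLabel.H: triangle(dom, 3.5),
            },
        )
        rep = check_variable_consistency(var)
        assert all(j.jump < 1e-9 for j in rep.jumps)

    def test_coverage_of_each_default_factor(self, kb):
        for var in kb.variables.values():
            rep = check_variable_consistency(var, grid_step=1e-3)
            assert rep.coverage >= 0.45
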