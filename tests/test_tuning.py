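"""Bell conversion, least-squares objective, bounded optimization."""

import numpy as np
import pytest

from fuzzycad import (
    BellMF,
    CombinerConfig,
    ContractError,
    DiagnosisClass,
    PatientRecord,
    TrainingExample,
    TuningConfig,
    apply_params,
    bell_class_membership_matrix,
    build_layout,
    class_memberships,
    flatten_params,
    pl_to_bell,
    tune,
    tuning_objective,
)

from .conftest import random_in_domain_vectors

SMOOTH = CombinerConfig(t_norm="product", s_norm="prob_sum")


@pytest.fixture(scope="module")
def bell_kb(kb):
    return pl_to_bell(kb)


def make_training(bell_kb, n, seed, config=SMOOTH):
    """Noise-free examples whose targets come from the generating model."""
    X = random_in_domain_vectors(n, seed)
    Y = bell_class_membership_matrix(X, bell_kb, config)
    return [
        TrainingExample(x=tuple(X[i]), y=tuple(Y[i])) for i in range(n)
    ]


class TestBellConversion:
    def test_all_terms_converted(self, bell_kb):
        assert all(
            isinstance(mf, BellMF)
            for var in bell_kb.variables.values()
            for mf in var.terms.values()
        )

    def test_peak_near_piecewise_argmax(self, kb, bell_kb):
        # the bell peak must sit where the printed term actually peaks
        from fuzzycad import TermLabel, evaluate_mf

        var = kb.variables["X3"]
        mf = bell_kb.variables["X3"].terms[TermLabel.A]
        assert evaluate_mf(var.terms[TermLabel.A], mf.b) >= 0.95

    def test_spread_positive_and_below_domain_width(self, bell_kb):
        for fid, var in bell_kb.variables.items():
            width = var.domain[1] - var.domain[0]
            for mf in var.terms.values():
                assert 0 < mf.c <= width

    def test_vectorized_pass_matches_scalar_engine(self, bell_kb):
        for config in (CombinerConfig(), SMOOTH):
            X = random_in_domain_vectors(25, seed=5)
            M = bell_class_membership_matrix(X, bell_kb, config)
            for i, row in enumerate(X):
                mus = class_memberships(
                    PatientRecord.from_values(*row), bell_kb, config
                )
                for j, cls in enumerate(DiagnosisClass):
                    assert M[i, j] == pytest.approx(mus[cls], abs=1e-14)


class TestObjective:
    def test_zero_at_generating_parameters(self, bell_kb):
        training = make_training(bell_kb, 50, seed=1)
        config = TuningConfig(what=frozenset({"b"}), combiners=SMOOTH)
        layout = build_layout(bell_kb, config)
        truth = flatten_params(bell_kb, layout)
        assert tuning_objective(truth, training, bell_kb, config, layout) == 0.0

    def test_single_example_total_miss_is_two(self, bell_kb):
        # model output (1,0,0,0) vs target (0,1,0,0): 1^2 + 1^2 = 2
        config = TuningConfig(what=frozenset({"w"}), combiners=SMOOTH)
        layout = build_layout(bell_kb, config)
        params = flatten_params(bell_kb, layout)
        training = [TrainingExample(x=(2.0, 2.0, 1.5, 3.0), y=DiagnosisClass.II)]
        X = np.array([training[0].x])
        pred = bell_class_membership_matrix(X, bell_kb, SMOOTH)[0]
        expected = float(((pred - np.array([0, 1, 0, 0])) ** 2).sum())
        assert tuning_objective(
            params, training, bell_kb, config, layout
        ) == pytest.approx(expected)

    def test_perturbing_b_strictly_increases_objective(self, bell_kb):
        training = make_training(bell_kb, 200, seed=2)
        config = TuningConfig(what=frozenset({"b"}), combiners=SMOOTH)
        layout = build_layout(bell_kb, config)
        truth = flatten_params(bell_kb, layout)
        for i in (0, len(truth) // 2, len(truth) - 1):
            bumped = truth.copy()
            bumped[i] += 0.05
            assert tuning_objective(bumped, training, bell_kb, config, layout) > 0

    def test_length_mismatch_rejected(self, bell_kb):
        training = make_training(bell_kb, 5, seed=3)
        config = TuningConfig(what=frozenset({"b"}), combiners=SMOOTH)
        with pytest.raises(ContractError):
            tuning_objective(np.zeros(3), training, bell_kb, config)


class TestTune:
    def test_noise_free_b_recovery(self, bell_kb):
        # 200 self-generated examples; b perturbed +/-10%; recovery within 5%
        training = make_training(bell_kb, 200, seed=42)
        config = TuningConfig(
            what=frozenset({"b"}),
            optimizer="lbfgsb",
            max_iter=500,
            seed=1,
            combiners=SMOOTH,
        )
        layout = build_layout(bell_kb, config)
        truth = flatten_params(bell_kb, layout)
        rng = np.random.default_rng(7)
        lo = np.array([b[0] for b in layout.bounds])
        hi = np.array([b[1] for b in layout.bounds])
        start = np.clip(truth * (1 + rng.uniform(-0.1, 0.1, truth.size)), lo, hi)
        result = tune(apply_params(bell_kb, layout, start), training, config)
        recovered = np.array([result.recovered_params[n] for n in layout.names])
        assert result.final_objective <= 1e-4
        assert (np.abs(recovered - truth) / np.abs(truth) <= 0.05).all()

    def test_max_iter_zero_is_a_no_op(self, bell_kb):
        training = make_training(bell_kb, 10, seed=4)
        config = TuningConfig(what=frozenset({"b", "c"}), max_iter=0, combiners=SMOOTH)
        layout = build_layout(bell_kb, config)
        result = tune(bell_kb, training, config)
        assert np.allclose(
            [result.recovered_params[n] for n in layout.names],
            flatten_params(bell_kb, layout),
        )
        assert result.final_objective == result.initial_objective

    @pytest.mark.parametrize("optimizer", ["nelder_mead", "lbfgsb", "random_restart"])
    def test_trajectory_non_increasing_and_final_not_worse(self, bell_kb, optimizer):
        training = make_training(bell_kb, 60, seed=5)
        config = TuningConfig(
            what=frozenset({"w"}),
            optimizer=optimizer,
            max_iter=60,
            seed=3,
            combiners=SMOOTH,
        )
        result = tune(bell_kb, training, config)
        traj = result.objective_trajectory
        assert all(a >= b for a, b in zip(traj, traj[1:]))
        assert result.final_objective <= result.initial_objective

    def test_bounds_respected(self, bell_kb):
        training = make_training(bell_kb, 40, seed=6)
        config = TuningConfig(
            optimizer="random_restart", max_iter=100, seed=9, combiners=SMOOTH
        )
        layout = build_layout(bell_kb, config)
        result = tune(bell_kb, training, config)
        for name, (lo, hi) in zip(layout.names, layout.bounds):
            assert lo <= result.recovered_params[name] <= hi

    def test_seed_determinism(self, bell_kb):
        training = make_training(bell_kb, 40, seed=8)
        config = TuningConfig(
            optimizer="random_restart", max_iter=80, seed=21, combiners=SMOOTH
        )
        r1 = tune(bell_kb, training, config)
        r2 = tune(bell_kb, training, config)
        assert r1.recovered_params == r2.recovered_params
        assert r1.objective_trajectory == r2.objective_trajectory

    def test_weights_of_contradicted_class_decrease(self, bell_kb):
        # label every class-III-looking region as class I: the tuner should
        # push class-III rule weights down relative to their start at 1
        X = random_in_domain_vectors(150, seed=10)
        M = bell_class_membership_matrix(X, bell_kb, SMOOTH)
        training = [
            TrainingExample(
                x=tuple(X[i]),
                y=DiagnosisClass.I
                if M[i].argmax() == 2
                else DiagnosisClass(int(M[i].argmax()) + 1),
            )
            for i in range(len(X))
        ]
        config = TuningConfig(
            what=frozenset({"w"}),
            optimizer="lbfgsb",
            max_iter=200,
            seed=2,
            combiners=SMOOTH,
        )
        result = tune(bell_kb, training, config)
        iii_idx = [
            i
            for i, r in enumerate(bell_kb.rules)
            if r.consequent == DiagnosisClass.III
        ]
        weights = [result.recovered_params[f"w[{i}]"] for i in iii_idx]
        assert all(w < 1.0 for w in weights)
        assert min(weights) < 0.5

    def test_empty_training_rejected(self, bell_kb):
        with pytest.raises(ContractError):
            tune(bell_kb, [], TuningConfig())

    def test_recovery_on_held_out_grid(self, bell_kb):
        # after tuning, model memberships match the generator on unseen points
        training = make_training(bell_kb, 200, seed=12)
        config = TuningConfig(
            what=frozenset({"b"}),
            optimizer="lbfgsb",
            max_iter=500,
            seed=1,
            combiners=SMOOTH,
        )
        layout = build_layout(bell_kb, config)
        truth = flatten_params(bell_kb, layout)
        rng = np.random.default_rng(13)
        lo = np.array([b[0] for b in layout.bounds])
        hi = np.array([b[1] for b in layout.bounds])
        start = np.clip(truth * (1 + rng.uniform(-0.08, 0.08, truth.size)), lo, hi)
        result = tune(apply_params(bell_kb, layout, start), training, config)
        holdout = random_in_domain_vectors(100, seed=99)
        want = bell_class_membership_matrix(holdout, bell_kb, SMOOTH)
        got = bell_class_membership_matrix(holdout, result.tuned_kb, SMOOTH)
        assert np.abs(want - got).max() <= 1e-3
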