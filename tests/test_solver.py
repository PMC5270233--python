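import numpy as np
import pytest
from scipy.optimize import minimize

import metasvm as ms
from metasvm import (
    CoefficientSet,
    PenaltyConfig,
    build_sqa_weights,
    decision_values,
    fit,
    hinge_identity_check,
    hinge_objective,
    smoothed_gradient_hessian,
    smoothed_objective,
)


def random_meta(rng, M=2, n=8, p=4):
    studies = []
    for m in range(M):
        X = rng.normal(size=(n, p))
        y = np.repeat([-1.0, 1.0], n // 2)
        studies.append(ms.StudyData(X, y, name=f"r{m}"))
    return ms.MetaDataset(studies, [f"f{j}" for j in range(p)])


class TestDecisionValues:
    def test_zero_coefficients_give_zero(self, toy_dataset):
        st = toy_dataset.studies[0]
        np.testing.assert_array_equal(
            decision_values(st, np.zeros(st.p + 1)), np.zeros(st.n)
        )

    def test_intercept_only(self, toy_dataset):
        st = toy_dataset.studies[0]
        np.testing.assert_array_equal(
            decision_values(st, np.r_[1.0, np.zeros(st.p)]), np.ones(st.n)
        )

    def test_hand_arithmetic(self):
        st = ms.StudyData(np.array([[2.0, -1.0]]), np.array([1.0]))
        assert decision_values(st, np.array([0.5, 1.0, 2.0]))[0] == pytest.approx(0.5)

    def test_dimension_mismatch(self, toy_dataset):
        with pytest.raises(ValueError):
            decision_values(toy_dataset.studies[0], np.zeros(3))


class TestHingeObjective:
    def test_zero_beta_counts_samples(self, toy_dataset):
        cfg = PenaltyConfig(lambda1=0.3, lambda2=0.3)
        beta = CoefficientSet.zeros(toy_dataset.M, toy_dataset.p)
        total_n = sum(st.n for st in toy_dataset.studies)
        assert hinge_objective(toy_dataset, beta, cfg) == pytest.approx(total_n)
        assert hinge_objective(
            toy_dataset, beta, cfg, normalized=True
        ) == pytest.approx(toy_dataset.M)

    def test_separated_data_zero_loss(self, separable_study):
        # margins >= 1 at beta = (0, 0.5, 0.5), no penalty
        beta = CoefficientSet(np.array([[0.0, 0.5, 0.5]]))
        cfg = PenaltyConfig()
        assert hinge_objective(separable_study, beta, cfg) == 0.0

    def test_single_study_reduces_to_l1_svm_objective(self, toy_dataset):
        # with M=1, lambda1=0 the objective is hinge sum + lambda2 * L1
        st = toy_dataset.studies[0]
        single = ms.MetaDataset([st], toy_dataset.feature_names)
        rng = np.random.default_rng(0)
        beta = CoefficientSet(rng.normal(size=(1, st.p + 1)))
        cfg = PenaltyConfig(lambda1=0.0, lambda2=0.7)
        margins = 1.0 - st.y * decision_values(st, beta.beta[0])
        expected = np.maximum(margins, 0).sum() + 0.7 * np.abs(beta.beta[0, 1:]).sum()
        assert hinge_objective(single, beta, cfg) == pytest.approx(expected)

    def test_positive_homogeneity_of_penalized_objective(self, toy_dataset):
        # kappa*(loss + lambda.P) == kappa*loss + (kappa*lambda).P
        rng = np.random.default_rng(1)
        beta = CoefficientSet(rng.normal(size=(toy_dataset.M, toy_dataset.p + 1)))
        cfg = PenaltyConfig(lambda1=0.4, lambda2=0.2)
        kappa = 3.7
        loss = hinge_objective(
            toy_dataset, beta, PenaltyConfig(lambda1=0, lambda2=0)
        )
        scaled = hinge_objective(
            toy_dataset, beta, cfg.with_lambdas(kappa * 0.4, kappa * 0.2)
        )
        plain = hinge_objective(toy_dataset, beta, cfg)
        assert scaled + (kappa - 1) * loss == pytest.approx(kappa * plain)


class TestHingeIdentity:
    @pytest.mark.parametrize("y, f, expected", [(1, 0.5, 0.5), (-1, 0.5, 1.5)])
    def test_hand_values(self, y, f, expected):
        lhs, rhs = hinge_identity_check(y, f)
        assert lhs == pytest.approx(expected)
        assert rhs == pytest.approx(expected)

    def test_identity_holds_for_random_inputs(self):
        rng = np.random.default_rng(2)
        for _ in range(1000):
            y = rng.choice([-1.0, 1.0])
            f = rng.normal(scale=3)
            lhs, rhs = hinge_identity_check(y, f)
            assert lhs == pytest.approx(rhs, abs=1e-14)

    def test_rejects_non_binary_label(self):
        with pytest.raises(ValueError):
            hinge_identity_check(0.5, 1.0)


class TestSQAWeights:
    def test_weight_values(self, toy_dataset):
        beta = CoefficientSet.zeros(toy_dataset.M, toy_dataset.p)
        state = build_sqa_weights(toy_dataset, beta, delta=1e-6)
        # beta = 0 makes every residual |y| = 1
        for w in state.weights:
            np.testing.assert_allclose(w, 1.0)

    def test_floor_caps_weight(self):
        # a sample sitting exactly on its label: residual 0 -> weight 1/delta
        X = np.array([[1.0], [0.0], [2.0], [0.0]])
        y = np.array([1.0, 1.0, -1.0, -1.0])
        data = ms.MetaDataset([ms.StudyData(X, y)], ["f"])
        beta = CoefficientSet(np.array([[0.0, 1.0]]))  # f = x
        state = build_sqa_weights(data, beta, delta=1e-6)
        w = state.weights[0]
        assert w[0] == pytest.approx(1e6)  # residual 0, floored
        assert w[1] == pytest.approx(1.0)
        assert w[2] == pytest.approx(1.0 / 3.0)  # residual -3


class TestSmoothedDerivatives:
    def _fd(self, func, x0, h):
        # 4th-order central differences for first and second derivative
        f = [func(x0 + k * h) for k in (-2, -1, 0, 1, 2)]
        g = (f[0] - 8 * f[1] + 8 * f[3] - f[4]) / (12 * h)
        hess = (-f[0] + 16 * f[1] - 30 * f[2] + 16 * f[3] - f[4]) / (12 * h * h)
        return g, hess

    def test_matches_finite_differences(self):
        rng = np.random.default_rng(4)
        cfg = PenaltyConfig(lambda1=0.6, lambda2=0.4, s=0.05, eps=1e-4)
        for trial in range(25):
            data = random_meta(rng)
            beta = CoefficientSet(rng.normal(size=(2, 5)))
            state = build_sqa_weights(data, beta, cfg.delta)
            m = trial % 2
            j = trial % 5

            def obj(x):
                b = beta.copy()
                b.beta[m, j] = x
                return smoothed_objective(data, b, state, cfg)

            g, h = smoothed_gradient_hessian(data, beta, state, cfg, m, j)
            g_fd, h_fd = self._fd(obj, beta.beta[m, j], 1e-3)
            assert g == pytest.approx(g_fd, rel=1e-5, abs=1e-7)
            assert h == pytest.approx(h_fd, rel=1e-5, abs=1e-7)
            assert h > 0

    def test_zero_beta_has_no_penalty_gradient(self):
        rng = np.random.default_rng(5)
        data = random_meta(rng)
        cfg = PenaltyConfig(lambda1=0.5, lambda2=0.5)
        beta = CoefficientSet.zeros(2, 4)
        state = build_sqa_weights(data, beta, cfg.delta)
        g_pen, _ = smoothed_gradient_hessian(data, beta, state, cfg, 0, 1)
        g_none, _ = smoothed_gradient_hessian(
            data, beta, state, PenaltyConfig(lambda1=0, lambda2=0), 0, 1
        )
        assert g_pen == pytest.approx(g_none, abs=1e-14)

    def test_majorizer_touches_hinge_at_expansion_point(self):
        rng = np.random.default_rng(6)
        data = random_meta(rng)
        cfg = PenaltyConfig(lambda1=0, lambda2=0, delta=1e-9)
        beta = CoefficientSet(0.1 * rng.normal(size=(2, 5)))
        state = build_sqa_weights(data, beta, cfg.delta)
        smoothed = smoothed_objective(data, beta, state, cfg)
        exact = hinge_objective(data, beta, cfg, normalized=True)
        assert smoothed == pytest.approx(exact, abs=1e-8)
        # and lies above it elsewhere
        for _ in range(20):
            other = CoefficientSet(beta.beta + 0.5 * rng.normal(size=(2, 5)))
            assert (
                smoothed_objective(data, other, state, cfg)
                >= hinge_objective(data, other, cfg, normalized=True) - 1e-10
            )


class TestFit:
    def test_huge_penalties_zero_everything(self, toy_dataset):
        res = fit(toy_dataset, PenaltyConfig(lambda1=1e6, lambda2=1e6))
        assert np.all(np.abs(res.coefficients.beta[:, 1:]) < 1e-6)
        assert not res.selected.any()
        assert not res.selected_union.any()

    def test_objective_trace_is_non_increasing(self, sim01):
        for l1, l2 in [(0.02, 0.01), (0.1, 0.05), (0.3, 0.0), (0.0, 0.15)]:
            res = fit(sim01.data, PenaltyConfig(lambda1=l1, lambda2=l2))
            tr = np.array(res.objective_trace)
            assert np.all(np.diff(tr) <= 1e-8 * (1.0 + np.abs(tr[:-1])))

    def test_separable_single_study_classifies_perfectly(self, separable_study):
        res = fit(separable_study, PenaltyConfig(lambda1=0.0, lambda2=0.01))
        st = separable_study.studies[0]
        f = decision_values(st, res.coefficients.beta[0])
        assert np.all(np.sign(f) == st.y)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_single_study_matches_generic_convex_solver(self, seed):
        # M=1, lambda1=0: the fit minimizes the plain L1-SVM objective; a
        # derivative-free solver on the same objective is the reference
        rng = np.random.default_rng(seed)
        n, p = 14, 3
        X = rng.normal(size=(n, p))
        y = np.repeat([-1.0, 1.0], n // 2)
        X[y > 0] += rng.uniform(0.3, 1.0, size=p)
        data = ms.MetaDataset([ms.StudyData(X, y)], [f"f{j}" for j in range(p)])
        cfg = PenaltyConfig(lambda1=0.0, lambda2=0.1, max_outer=2000,
                            stab_tol=1e-8, tol=1e-9)
        ours = fit(data, cfg)
        obj_ours = hinge_objective(data, ours.coefficients, cfg, normalized=True)

        def ref_obj(b):
            margins = 1.0 - y * (b[0] + X @ b[1:])
            return np.maximum(margins, 0).mean() + 0.1 * np.abs(b[1:]).sum()

        best = np.inf
        for x0 in (np.zeros(p + 1), ours.coefficients.beta[0]):
            r = minimize(ref_obj, x0, method="Powell",
                         options=dict(maxiter=20000, xtol=1e-10, ftol=1e-12))
            best = min(best, r.fun)
        assert abs(obj_ours - best) < 1e-3

    def test_permuting_studies_permutes_coefficients(self, sim01):
        cfg = PenaltyConfig(lambda1=0.08, lambda2=0.02, tol=1e-10,
                            stab_tol=1e-8, max_outer=500)
        res = fit(sim01.data, cfg)
        perm = [2, 0, 1]
        permuted = ms.MetaDataset(
            [sim01.data.studies[i] for i in perm], sim01.data.feature_names
        )
        res_p = fit(permuted, cfg)
        np.testing.assert_allclose(
            res_p.coefficients.beta, res.coefficients.beta[perm], atol=2e-4
        )

    def test_group_only_penalty_selects_genes_jointly(self, sim01):
        # with lambda2 = 0 a feature's coefficients enter or leave the model
        # through their shared group norm: study-level masks agree gene-wise
        for l1 in (0.1, 0.2, 0.4):
            res = fit(sim01.data, PenaltyConfig(lambda1=l1, lambda2=1e-12))
            any_sel = res.selected.any(axis=0)
            all_sel = res.selected.all(axis=0)
            disagree = np.mean(any_sel != all_sel)
            assert disagree <= 0.1

    def test_init_shape_is_checked(self, toy_dataset):
        with pytest.raises(ValueError):
            fit(toy_dataset, PenaltyConfig(), init=CoefficientSet.zeros(3, 4))
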