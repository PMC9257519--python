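"""Feature expansion, default penalties, the L1 maxent fit, and predictions."""

import numpy as np
import pytest
from scipy.optimize import minimize

from rangeshift.maxent import (
    FeatureExpansion,
    MaxEntModel,
    default_beta,
    fit_maxent,
    fit_maxent_values,
    objective,
    predict_cloglog,
    predict_raw,
)


def lbfgs_oracle(P, B, beta):
    """Independent minimizer of the penalized objective via the split-sign
    reformulation lambda = u - v, u, v >= 0 (the L1 term becomes linear),
    solved with L-BFGS-B."""
    d = P.shape[1]
    emp = P.mean(axis=0)

    def f(z):
        lam = z[:d] - z[d:]
        eta = B @ lam
        mx = eta.max()
        lse = mx + np.log(np.exp(eta - mx).sum())
        p = np.exp(eta - lse)
        grad_lam = B.T @ p - emp
        val = -emp @ lam + lse + beta @ (z[:d] + z[d:])
        return val, np.concatenate([grad_lam + beta, -grad_lam + beta])

    res = minimize(
        f, np.zeros(2 * d), jac=True, method="L-BFGS-B",
        bounds=[(0, None)] * (2 * d),
        options={"maxiter": 20_000, "ftol": 1e-16, "gtol": 1e-12},
    )
    return res.x[:d] - res.x[d:]


def simple_expansion(d=1):
    return FeatureExpansion(
        feature_class="L",
        continuous=tuple((f"v{j}", 0.0, 1.0) for j in range(d)),
    )


class TestFeatureExpansion:
    @pytest.mark.parametrize(
        "fc, value, expected",
        [
            ("LQ", 0.0, [0.0, 0.0]),
            ("LQ", 1.0, [1.0, 1.0]),
            ("Q", 0.5, [0.25]),
            ("L", 0.5, [0.5]),
        ],
    )
    def test_scaling_and_class(self, fc, value, expected):
        exp = FeatureExpansion(feature_class=fc, continuous=(("v", 0.0, 1.0),))
        assert exp.transform({"v": [value]})[0].tolist() == expected

    def test_prediction_values_clamped_into_range(self):
        exp = FeatureExpansion(feature_class="L", continuous=(("v", 2.0, 4.0),))
        out = exp.transform({"v": [0.0, 6.0]})
        assert out[:, 0].tolist() == [0.0, 1.0]

    def test_categorical_one_hot(self):
        exp = FeatureExpansion(
            feature_class="L", categorical=(("sed", (1.0, 2.0, 3.0)),)
        )
        assert exp.transform({"sed": [2.0]})[0].tolist() == [0.0, 1.0, 0.0]

    def test_unseen_level_warns_and_zeroes(self):
        exp = FeatureExpansion(
            feature_class="L", categorical=(("sed", (1.0, 2.0)),)
        )
        with pytest.warns(UserWarning, match="unseen"):
            out = exp.transform({"sed": [9.0]})
        assert out[0].tolist() == [0.0, 0.0]

    def test_degenerate_range_rejected(self):
        with pytest.raises(ValueError):
            FeatureExpansion(feature_class="L", continuous=(("v", 1.0, 1.0),))


class TestDefaultBeta:
    def test_linear_in_rm(self, rng):
        exp = simple_expansion(3)
        F = rng.random((40, 3))
        b1 = default_beta(exp, 40, 1.0, F)
        b2 = default_beta(exp, 40, 2.0, F)
        assert np.allclose(b2, 2.0 * b1)

    def test_zero_variance_floored_positive(self):
        exp = simple_expansion(1)
        F = np.full((20, 1), 0.7)
        b = default_beta(exp, 20, 1.0, F)
        assert b[0] > 0

    def test_sqrt_v_over_m_scaling(self, rng):
        # quadrupling m at fixed variance and fixed tau halves beta
        exp = simple_expansion(1)
        F = rng.random((100, 1))
        v = F.var(axis=0)
        from rangeshift.maxent import TAU_CONTINUOUS, _interp_tau

        for m in (200, 800):
            expected = 1.0 * _interp_tau(m, TAU_CONTINUOUS) * np.sqrt(v / m)
            assert np.allclose(default_beta(exp, m, 1.0, F), expected)
        b200 = default_beta(exp, 200, 1.0, F)
        b800 = default_beta(exp, 800, 1.0, F)
        # tau is clamped beyond m=100, so only the sqrt(1/m) factor remains
        assert np.allclose(b800, 0.5 * b200)


class TestFitClosedForms:
    def test_empty_expansion_is_uniform(self):
        exp = FeatureExpansion(feature_class="L")
        model = fit_maxent(np.zeros((3, 0)), np.zeros((7, 0)), exp)
        raw = predict_raw(model, np.zeros((7, 0)))
        assert np.allclose(raw, 1.0 / 7)
        assert model.entropy == pytest.approx(np.log(7))

    def test_two_cell_kkt_solution(self):
        # all presences at f=1, background {0, 1}, beta=0.1:
        # stationarity gives E_model[f] = 1 - 0.1 = 0.9, lambda = ln 9
        exp = simple_expansion()
        model = fit_maxent(
            np.ones((5, 1)), np.array([[0.0], [1.0]]), exp,
            beta=np.array([0.1]), tol=1e-10,
        )
        assert model.lam[0] == pytest.approx(np.log(9.0), abs=1e-4)
        raw = predict_raw(model, np.array([[0.0], [1.0]]))
        assert raw[1] == pytest.approx(0.9, abs=1e-4)

    def test_balanced_presences_give_zero_coefficient(self):
        exp = simple_expansion()
        P = np.array([[0.0], [1.0]] * 5)
        B = np.array([[0.0], [1.0]])
        model = fit_maxent(P, B, exp, beta=np.array([0.0]), tol=1e-10)
        assert model.lam[0] == pytest.approx(0.0, abs=1e-6)
        assert np.allclose(predict_raw(model, B), 0.5, atol=1e-6)


class TestFitProperties:
    def make_problem(self, rng, n_bg=40, d=2):
        B = rng.random((n_bg, d))
        P = B[rng.choice(n_bg, 15)] + 0.01 * rng.random((15, d))
        P = np.clip(P, 0, 1)
        return P, B

    def test_oracle_equivalence_small_landscapes(self, rng):
        exp = simple_expansion(2)
        for _ in range(3):
            P, B = self.make_problem(rng)
            beta = rng.uniform(0.01, 0.1, 2)
            model = fit_maxent(P, B, exp, beta=beta, tol=1e-10)
            lam_o = lbfgs_oracle(P, B, beta)
            assert np.max(np.abs(model.lam - lam_o)) < 1e-3
            assert abs(
                objective(model.lam, P, B, beta) - objective(lam_o, P, B, beta)
            ) < 1e-8

    def test_fit_never_worse_than_null(self, rng):
        exp = simple_expansion(3)
        P, B = self.make_problem(rng, d=3)
        model = fit_maxent(P, B, exp, rm=1.0)
        assert objective(model.lam, P, B, model.beta) <= objective(
            np.zeros(3), P, B, model.beta
        ) + 1e-12

    def test_rm_weakly_shrinks_l1_norm(self, rng):
        exp = simple_expansion(2)
        P, B = self.make_problem(rng)
        norms = [
            np.abs(fit_maxent(P, B, exp, rm=rm, tol=1e-9).lam).sum()
            for rm in (0.5, 1.0, 2.0, 4.0)
        ]
        assert all(a >= b - 1e-6 for a, b in zip(norms, norms[1:]))

    def test_background_order_invariance(self, rng):
        exp = simple_expansion(2)
        P, B = self.make_problem(rng)
        perm = rng.permutation(len(B))
        m1 = fit_maxent(P, B, exp, rm=1.0, tol=1e-9)
        m2 = fit_maxent(P, B[perm], exp, rm=1.0, tol=1e-9)
        assert np.allclose(m1.lam, m2.lam, atol=1e-6)

    def test_raw_shift_invariance(self, rng):
        # adding a constant to one feature everywhere leaves raw unchanged
        exp = simple_expansion(2)
        P, B = self.make_problem(rng)
        beta = np.array([0.05, 0.05])
        m1 = fit_maxent(P, B, exp, beta=beta, tol=1e-10)
        shift = np.array([0.3, 0.0])
        m2 = fit_maxent(P + shift, B + shift, exp, beta=beta, tol=1e-10)
        assert np.allclose(
            predict_raw(m1, B), predict_raw(m2, B + shift), atol=1e-5
        )


class TestPredictions:
    def test_raw_sums_to_one_over_background(self, rng):
        exp = simple_expansion(2)
        B = rng.random((30, 2))
        P = rng.random((10, 2))
        model = fit_maxent(P, B, exp, rm=1.0)
        assert predict_raw(model, B).sum() == pytest.approx(1.0, abs=1e-9)

    def test_cloglog_of_uniform_model(self):
        exp = FeatureExpansion(feature_class="L")
        model = fit_maxent(np.zeros((3, 0)), np.zeros((25, 0)), exp)
        c = predict_cloglog(model, np.zeros((25, 0)))
        assert np.allclose(c, 1.0 - np.exp(-1.0), atol=1e-6)

    def test_cloglog_preserves_raw_ranking(self, rng):
        exp = simple_expansion(2)
        B = rng.random((40, 2))
        model = fit_maxent(rng.random((12, 2)), B, exp, rm=1.0)
        raw = predict_raw(model, B)
        clog = predict_cloglog(model, B)
        assert np.array_equal(np.argsort(raw), np.argsort(clog))

    def test_zero_raw_maps_to_zero(self):
        exp = FeatureExpansion(feature_class="L")
        model = fit_maxent(np.zeros((2, 0)), np.zeros((5, 0)), exp)
        assert 1.0 - np.exp(-np.exp(model.entropy) * 0.0) == 0.0


class TestSerialization:
    def test_json_roundtrip(self, rng):
        model = fit_maxent_values(
            {"v": rng.random(20), "sed": rng.choice([1.0, 2.0], 20)},
            {"v": rng.random(100), "sed": rng.choice([1.0, 2.0], 100)},
            feature_class="LQ",
            categorical={"sed": (1.0, 2.0)},
            rm=1.5,
        )
        clone = MaxEntModel.from_json(model.to_json())
        assert np.allclose(clone.lam, model.lam)
        assert clone.expansion == model.expansion
        assert clone.entropy == pytest.approx(model.entropy)
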