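"""Marginal likelihood, score, fitting and prediction.

The dense-integration oracles here are written independently of the
adaptive-quadrature engine: plain trapezoid integration over the random
effect on a wide grid, and a classical Gaussian random-intercept likelihood
via non-adaptive Gauss-Hermite.
"""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import expit

from hcam.data import HospitalDataset
from hcam.model import (
    ModelParams,
    _layout,
    _marginal,
    _pack,
    empirical_bayes_effects,
    fit,
    hcam_marginal_loglik,
    predict_mortality,
    zib_marginal_loglik,
)
from hcam.simulate import ScenarioSpec, generate
from hcam.snp import SNPDensityParams, snp_pdf
from hcam.splines import SplineBasisSpec, build_basis


def flat_basis():
    """A degree-0 single-column basis whose centered column is identically
    zero: the spline term contributes nothing, whatever gamma is."""
    return SplineBasisSpec(degree=0, q=0, knots=np.array([0.0, 1.0]),
                          domain=(0.0, 1.0), centering_offsets=np.array([1.0]))


def tiny_dataset(with_T=True):
    X = np.array([[0.5, -1.0, 0.2], [1.0, 0.3, -0.5]])
    T = np.array([[1.0, 0.2], [1.0, -0.4]]) if with_T else None
    return HospitalDataset(hospital_ids=["a", "a"], y=[1, 0], X=X, V=[0.3], T=T)


def trapezoid_loglik(data, params, basis, model):
    """Dense-grid integration oracle for a single-cluster likelihood."""
    b = np.linspace(-8, 8, 20001)
    Bg = basis.design(data.V) @ params.gamma
    kap = b[:, None] + Bg[data.hospital_index][None, :] + (data.X @ params.beta)[None, :]
    if model == "zib":
        tau = data.T @ params.theta
        t = (data.y * (tau + kap)
             + (1 - data.y) * np.log(1 + np.exp(tau) + np.exp(kap))
             - np.log1p(np.exp(tau)) - np.log1p(np.exp(kap)))
    else:
        t = data.y * kap - np.log1p(np.exp(kap))
    integrand = np.exp(t.sum(axis=1)) * snp_pdf(b, params.snp)
    return float(np.log(np.trapezoid(integrand, b)))


class TestLikelihoodOracles:
    @pytest.mark.parametrize("K,angles", [(0, []), (1, [0.5]), (2, [0.3, -0.7])])
    @pytest.mark.parametrize("model", ["hcam", "zib"])
    def test_agq_matches_dense_trapezoid(self, K, angles, model):
        data = tiny_dataset()
        params = ModelParams(
            beta=np.array([0.8, -0.3, 1.2]), gamma=np.array([0.4]),
            snp=SNPDensityParams(K=K, a=0.2, sigma=1.1, angles=angles),
            theta=np.array([0.5, -1.0]) if model == "zib" else None,
        )
        f = zib_marginal_loglik if model == "zib" else hcam_marginal_loglik
        ll = f(data, params, flat_basis(), n_quad=21)
        oracle = trapezoid_loglik(data, params, flat_basis(), model)
        assert ll == pytest.approx(oracle, rel=1e-6)

    def test_zib_saturated_inflation_equals_hcam(self):
        # theta intercept +30 forces rho ~ 1: the zero-inflated likelihood
        # collapses onto the plain Bernoulli mixed-model likelihood
        X = np.array([[0.5, -1.0, 0.2]])
        data1 = HospitalDataset(hospital_ids=["a"], y=[0], X=X, V=[0.3],
                                T=np.ones((1, 1)))
        params = ModelParams(beta=np.array([0.8, -0.3, 1.2]), gamma=np.array([0.0]),
                             snp=SNPDensityParams(K=0, a=0.0, sigma=1.0),
                             theta=np.array([30.0]))
        llz = zib_marginal_loglik(data1, params, flat_basis(), n_quad=21)
        llh = hcam_marginal_loglik(data1, params, flat_basis(), n_quad=21)
        assert llz == pytest.approx(llh, abs=1e-8)

    def test_saturated_all_zero_outcomes(self):
        # a = -30, sigma = 0.01: P(Y=0) ~ 1 for every patient, loglik ~ 0
        X = np.zeros((6, 2))
        data = HospitalDataset(hospital_ids=["a"] * 3 + ["b"] * 3, y=np.zeros(6),
                               X=X, V=[0.2, 0.8])
        params = ModelParams(beta=np.zeros(2), gamma=np.array([0.0]),
                             snp=SNPDensityParams(K=0, a=-30.0, sigma=0.01))
        ll = hcam_marginal_loglik(data, params, flat_basis(), n_quad=21)
        assert abs(ll) < 1e-8

    def test_classical_glmm_comparator(self):
        """K=0 with the hospital attribute as a linear (per-row) covariate
        equals an independently coded random-intercept logistic likelihood."""
        rng = np.random.default_rng(8)
        H, n_h = 6, 8
        ids = np.repeat([f"h{i}" for i in range(H)], n_h)
        V = rng.uniform(0, 1, H)
        X = rng.normal(size=(H * n_h, 2))
        Xa = np.column_stack([X, V[np.repeat(np.arange(H), n_h)]])  # V as covariate
        y = rng.integers(0, 2, H * n_h)
        data = HospitalDataset(hospital_ids=ids, y=y, X=Xa, V=V)
        beta = np.array([0.6, -0.4, 0.9])  # last entry = linear V effect
        a, sigma = -0.3, 0.8
        params = ModelParams(beta=beta, gamma=np.array([0.0]),
                             snp=SNPDensityParams(K=0, a=a, sigma=sigma))
        ll = hcam_marginal_loglik(data, params, flat_basis(), n_quad=31)

        # independent: non-adaptive Gauss-Hermite, 201 nodes
        xq, wq = np.polynomial.hermite.hermgauss(201)
        total = 0.0
        for h in range(H):
            rows = slice(h * n_h, (h + 1) * n_h)
            eta = Xa[rows] @ beta
            bh = a + np.sqrt(2) * sigma * xq
            kap = bh[:, None] + eta[None, :]
            t = y[rows] * kap - np.log1p(np.exp(kap))
            total += np.log(np.sum(wq / np.sqrt(np.pi) * np.exp(t.sum(axis=1))))
        assert ll == pytest.approx(total, abs=1e-8)

    def test_invalid_nquad_rejected(self):
        data = tiny_dataset()
        params = ModelParams(beta=np.zeros(3), gamma=np.array([0.0]),
                             snp=SNPDensityParams(K=0, a=0, sigma=1))
        with pytest.raises(ValueError):
            hcam_marginal_loglik(data, params, flat_basis(), n_quad=2)


class TestScore:
    def test_analytic_score_matches_central_differences(self):
        spec = ScenarioSpec(scenario="ZIB", H=15, n_h=12, seed=3, theta=-2.0)
        data, _ = generate(spec)
        basis, design = build_basis(data.V, d=3, q=3)
        layout = _layout(3, 7, 2, 2)
        rng = np.random.default_rng(1)
        x = _pack(rng.normal(0, 0.5, 3), rng.normal(0, 0.3, 7), 0.1, -0.2,
                  [0.4, -0.6], [0.3, 0.2])
        _, grad = _marginal(data, "zib", x, layout, design, 21, want_grad=True)
        for i in range(len(x)):
            e = np.zeros_like(x); e[i] = 1e-6
            vp, _ = _marginal(data, "zib", x + e, layout, design, 21)
            vm, _ = _marginal(data, "zib", x - e, layout, design, 21)
            num = (vp - vm) / 2e-6
            assert grad[i] == pytest.approx(num, rel=2e-5, abs=1e-7)


@settings(derandomize=True, max_examples=60, deadline=None)
@given(st.floats(-20, 20), st.floats(-20, 20))
def test_two_status_exponent_identity(tau, kappa):
    """The marginalized exponent reproduces P(Y=1) = rho*pi exactly."""
    rho, pi = expit(tau), expit(kappa)
    l1 = (tau + kappa) - np.logaddexp(0, tau) - np.logaddexp(0, kappa)
    l0 = (np.logaddexp(np.logaddexp(0, tau), kappa)
          - np.logaddexp(0, tau) - np.logaddexp(0, kappa))
    assert np.exp(l1) == pytest.approx(rho * pi, abs=1e-12)
    assert np.exp(l0) == pytest.approx(1 - rho * pi, abs=1e-12)


class TestFitting:
    def test_quadrature_stability(self, small_scenario, small_fit):
        data, _ = small_scenario
        ll15 = hcam_marginal_loglik(data, small_fit.params, small_fit.basis, n_quad=15)
        ll41 = hcam_marginal_loglik(data, small_fit.params, small_fit.basis, n_quad=41)
        assert abs(ll15 - ll41) / abs(ll41) < 1e-4

    def test_information_criteria_consistent(self, small_fit):
        assert small_fit.aic == pytest.approx(-2 * small_fit.loglik + 2 * small_fit.n_free)
        assert small_fit.bic == pytest.approx(
            -2 * small_fit.loglik + small_fit.n_free * np.log(40 * 25))

    def test_nested_likelihood_never_decreases(self):
        spec = ScenarioSpec(scenario="A", H=40, n_h=25, re_dist="lognormal", seed=21)
        data, _ = generate(spec)
        res = fit(data, model="hcam", K_grid=(0, 1, 2))
        lls = {r["K"]: r["loglik"] for r in res.k_table}
        assert lls[1] >= lls[0] - 1e-6
        assert lls[2] >= lls[1] - 1e-6
        assert res.loglik >= lls[0] - 1e-6

    def test_parameter_recovery_normal_truth(self, small_scenario, small_fit):
        _, truth = small_scenario
        rd = np.linalg.norm(small_fit.params.beta - truth["beta"]) / np.linalg.norm(truth["beta"])
        assert rd < 0.1
        assert abs(small_fit.random_effect_mean) < 0.5
        assert 0.4 < small_fit.random_effect_variance < 1.8

    def test_gaussian_truth_selects_k0_by_bic(self):
        """Data from a normal random effect: BIC keeps the Gaussian density
        in the large majority of replicates."""
        picks = []
        for r in range(10):
            spec = ScenarioSpec(scenario="A", H=100, n_h=30, re_dist="normal",
                                seed=700 + r)
            data, _ = generate(spec)
            res = fit(data, model="hcam", K_grid=(0, 2), selection="bic")
            picks.append(res.params.snp.K)
        assert np.mean(np.array(picks) == 0) >= 0.8

    def test_zib_nests_hcam_when_inflation_saturates(self):
        """Data with no zero-inflation, T = intercept only: the fitted ZIB
        mortality coefficients agree with the plain HCAM fit."""
        spec = ScenarioSpec(scenario="A", H=30, n_h=25, re_dist="normal", seed=5)
        data, _ = generate(spec)
        data_t = HospitalDataset(hospital_ids=data.hospital_ids, y=data.y,
                                 X=data.X, V=data.V, T=np.ones((data.N, 1)))
        res_h = fit(data, model="hcam", K_grid=(0,))
        res_z = fit(data_t, model="zib", K_grid=(0,))
        assert np.allclose(res_z.params.beta, res_h.params.beta, atol=0.1)
        assert res_z.params.theta[0] > 2.0  # rho pushed toward 1

    def test_flat_outcome_hospital_warns(self):
        rng = np.random.default_rng(0)
        ids = np.repeat(["a", "b", "c", "d"], 10)
        y = rng.integers(0, 2, 40)
        y[:10] = 0  # hospital a has no events
        data = HospitalDataset(hospital_ids=ids, y=y, X=rng.normal(size=(40, 2)),
                               V=[0.1, 0.4, 0.7, 0.9])
        with pytest.warns(UserWarning, match="outcome variation"):
            fit(data, model="hcam", K_grid=(0,), d=1, q=0)


class TestPrediction:
    def test_neutral_parameters_give_half(self):
        res_like = _neutral_fit()
        p = predict_mortality(res_like, np.zeros((1, 2)), hospital=0)
        assert p[0] == pytest.approx(0.5)

    def test_zib_product_form(self):
        res_like = _neutral_fit(model="zib", theta=np.array([0.0]))
        p = predict_mortality(res_like, np.zeros((1, 2)), T=np.ones((1, 1)), hospital=0)
        assert p[0] == pytest.approx(0.25)  # rho = pi = 1/2

    def test_monotone_in_positive_coefficient(self, small_fit):
        x = np.zeros((25, 3))
        x[:, 0] = np.linspace(-2, 2, 25)  # beta_1 = 3 > 0 in truth; fitted > 0
        p = predict_mortality(small_fit, x, hospital=3)
        assert np.all(np.diff(p) >= 0)

    def test_missing_T_rejected_for_zib(self):
        res_like = _neutral_fit(model="zib", theta=np.array([0.0]))
        with pytest.raises(ValueError):
            predict_mortality(res_like, np.zeros((1, 2)), hospital=0)


def _neutral_fit(model="hcam", theta=None):
    from hcam.model import FitResult

    basis = flat_basis()
    params = ModelParams(beta=np.zeros(2), gamma=np.array([0.0]),
                         snp=SNPDensityParams(K=0, a=0.0, sigma=1.0), theta=theta)
    return FitResult(model=model, params=params, basis=basis,
                     hospital_ids=np.array(["a"]), V=np.array([0.5]),
                     loglik=0.0, aic=0.0, bic=0.0, n_quad_points=21,
                     converged=True, iterations=0, random_effect_mean=0.0,
                     random_effect_variance=1.0, b_modes=np.array([0.0]))


class TestEmpiricalBayes:
    def test_mode_near_truth_on_informative_cluster(self):
        # one hospital with many observations pins its effect
        rng = np.random.default_rng(3)
        n = 4000
        X = rng.normal(size=(n, 1))
        b_true = 1.3
        y = (rng.random(n) < expit(b_true + 0.5 * X[:, 0])).astype(float)
        data = HospitalDataset(hospital_ids=["a"] * n, y=y, X=X, V=[0.5])
        params = ModelParams(beta=np.array([0.5]), gamma=np.array([0.0]),
                             snp=SNPDensityParams(K=0, a=0.0, sigma=2.0))
        mode = empirical_bayes_effects(data, params, flat_basis())
        assert mode[0] == pytest.approx(b_true, abs=0.15)

    def test_mean_and_mode_agree_for_symmetric_posterior(self, small_scenario, small_fit):
        data, _ = small_scenario
        modes = empirical_bayes_effects(data, small_fit.params, small_fit.basis)
        means = empirical_bayes_effects(data, small_fit.params, small_fit.basis,
                                        method="mean")
        assert np.corrcoef(modes, means)[0, 1] > 0.99
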