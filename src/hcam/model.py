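"""Maximum-likelihood fitting of hospital-compare additive models.

Two model families share one marginal-likelihood engine:

* HCAM — logistic mixed model ``logit(p_hj) = b_h + B(V_h)^T gamma +
  X_hj^T beta`` with an SNP random hospital effect ``b_h ~ g_K``.  There is
  no free global intercept: the location ``a`` of ``g_K`` plays that role.
* ZI-HCAM — a zero-inflated Bernoulli layer on top: a latent at-risk
  indicator ``S`` with ``logit(rho_hj) = T_hj^T theta`` multiplies the
  at-risk mortality probability, ``P(Y=1) = rho * pi``.

Each cluster contributes ``log \\int exp(sum_j l_j(b)) g_K(b) db``, evaluated
by adaptive Gauss-Hermite quadrature: nodes are recentered and rescaled at
the mode and curvature of the Gaussian-base log-integrand (Laplace
adaptation), with the squared SNP polynomial folded into the node weights,
and the sum assembled by log-sum-exp.  The score is the posterior
expectation of the complete-data score on the same nodes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit

from .data import HospitalDataset
from .snp import (
    SNPDensityParams,
    _spherical,
    _spherical_jacobian,
    _sqrt_psd,
    coefficients_to_angles,
    hermite_moment_matrix,
    snp_moments,
)
from .splines import SplineBasisSpec, build_basis

__all__ = [
    "ModelParams",
    "FitResult",
    "hcam_marginal_loglik",
    "zib_marginal_loglik",
    "fit",
    "predict_mortality",
    "empirical_bayes_effects",
]

_LOG_2PI = np.log(2 * np.pi)


@dataclass
class ModelParams:
    """Parameter set of an HCAM (theta is None) or ZI-HCAM fit."""

    beta: np.ndarray
    gamma: np.ndarray
    snp: SNPDensityParams
    theta: np.ndarray | None = None

    def to_dict(self) -> dict:
        d = {
            "beta": [float(x) for x in np.atleast_1d(self.beta)],
            "gamma": [float(x) for x in np.atleast_1d(self.gamma)],
            "snp": self.snp.to_dict(),
            "theta": None if self.theta is None else [float(x) for x in np.atleast_1d(self.theta)],
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        return cls(
            beta=np.asarray(d["beta"], dtype=float),
            gamma=np.asarray(d["gamma"], dtype=float),
            snp=SNPDensityParams.from_dict(d["snp"]),
            theta=None if d.get("theta") is None else np.asarray(d["theta"], dtype=float),
        )

    @property
    def n_free(self) -> int:
        n = len(np.atleast_1d(self.beta)) + len(np.atleast_1d(self.gamma)) + 2 + self.snp.K
        if self.theta is not None:
            n += len(np.atleast_1d(self.theta))
        return n


@dataclass
class FitResult:
    """A fitted model plus diagnostics and per-hospital random-effect modes."""

    model: str  # "hcam" | "zib"
    params: ModelParams
    basis: SplineBasisSpec
    hospital_ids: np.ndarray
    V: np.ndarray
    loglik: float
    aic: float
    bic: float
    n_quad_points: int
    converged: bool
    iterations: int
    random_effect_mean: float
    random_effect_variance: float
    b_modes: np.ndarray
    n_free: int = 0  # effective free parameters behind aic/bic
    k_table: list = field(default_factory=list)
    per_k: dict = field(default_factory=dict)

    def f_values(self, v) -> np.ndarray:
        """Fitted hospital fixed effect at attribute values ``v``."""
        return self.basis.design(v) @ self.params.gamma


# --------------------------------------------------------------------------
# per-patient log-likelihood terms and derivatives
# --------------------------------------------------------------------------

def _bernoulli_terms(kappa, y, derivs=False):
    """log Bernoulli(expit(kappa)) mass at y, plus d/dkappa terms."""
    ll = y * kappa - np.logaddexp(0.0, kappa)
    if not derivs:
        return ll, None, None
    p = expit(kappa)
    return ll, y - p, -p * (1.0 - p)


def _zib_terms(kappa, tau, y, derivs=False):
    """Marginalized two-status terms: Y ~ 0 w.p. 1-rho, Bern(pi) w.p. rho.

    l = Y (tau + kappa) + (1-Y) log(1 + e^tau + e^kappa)
        - log(1 + e^tau) - log(1 + e^kappa)
    which equals log(rho pi) for Y=1 and log(1 - rho pi) for Y=0.
    """
    log1t = np.logaddexp(0.0, tau)
    log1k = np.logaddexp(0.0, kappa)
    L = np.logaddexp(log1t, kappa)  # log(1 + e^tau + e^kappa)
    ll = y * (tau + kappa) + (1.0 - y) * L - log1t - log1k
    if not derivs:
        return ll, None, None, None
    dk = y + (1.0 - y) * np.exp(kappa - L) - expit(kappa)
    dt = y + (1.0 - y) * np.exp(tau - L) - expit(tau)
    d2k = (1.0 - y) * np.exp(log1t + kappa - 2.0 * L) - expit(kappa) * expit(-kappa)
    return ll, dk, dt, d2k


def _row_terms(model, kappa, tau, y, derivs=False):
    if model == "zib":
        return _zib_terms(kappa, tau, y, derivs)
    ll, dk, d2k = _bernoulli_terms(kappa, y, derivs)
    return ll, dk, None, d2k


# --------------------------------------------------------------------------
# adaptive quadrature engine
# --------------------------------------------------------------------------

def _find_modes(data, model, offset, tau, a, sigma, b0=None, max_iter=40, tol=1e-9):
    """Vectorized damped Newton for the per-cluster Gaussian-base mode.

    Maximizes psi_h(b) = sum_j l_j(b) - (b - a)^2 / (2 sigma^2) over b for
    every hospital simultaneously.  Returns (mode, curvature) with
    curvature = -psi'' at the mode (floored away from zero).
    """
    H = data.H
    b = np.full(H, a, dtype=float) if b0 is None else b0.copy()

    def psi_and_derivs(b):
        kappa = b[data.hospital_index] + offset
        ll, dk, _, d2k = _row_terms(model, kappa, tau, data.y, derivs=True)
        val = data.group_sum(ll) - (b - a) ** 2 / (2 * sigma**2)
        grad = data.group_sum(dk) - (b - a) / sigma**2
        hess = data.group_sum(d2k) - 1.0 / sigma**2
        return val, grad, hess

    val, grad, hess = psi_and_derivs(b)
    for _ in range(max_iter):
        h_safe = np.minimum(hess, -1e-10)
        step = -grad / h_safe
        np.clip(step, -4 * sigma, 4 * sigma, out=step)
        # backtracking: accept only improving steps (vectorized halving)
        t = np.ones(H)
        for _ in range(8):
            cand = b + t * step
            v2, g2, h2 = psi_and_derivs(cand)
            worse = v2 < val - 1e-12
            if not worse.any():
                break
            t[worse] *= 0.5
        accept = v2 >= val - 1e-12
        b = np.where(accept, cand, b)
        val = np.where(accept, v2, val)
        grad = np.where(accept, g2, grad)
        hess = np.where(accept, h2, hess)
        if np.max(np.abs(grad) * sigma**2) < tol:
            break
    curv = np.maximum(-hess, 1e-8)
    return b, curv


def _marginal(data, model, params_vec, layout, basis_design, n_quad, mode_cache=None,
              want_grad=False):
    """Marginal log-likelihood (and score) at a packed parameter vector."""
    beta, gamma, a, log_sigma, angles, theta = _unpack(params_vec, layout)
    sigma = np.exp(log_sigma)
    K = len(angles)

    # raw (unflipped) polynomial coefficients and their angle-Jacobian; the
    # density only involves P^2 so the sign convention is irrelevant here
    if K > 0:
        A = hermite_moment_matrix(K)
        Asq = _sqrt_psd(A)
        c = _spherical(angles)
        xi = np.linalg.solve(Asq, c)
        dxi = np.linalg.solve(Asq, _spherical_jacobian(angles)) if want_grad else None
    else:
        xi = np.array([1.0])
        dxi = None

    offset = data.X @ beta + (basis_design @ gamma)[data.hospital_index]
    tau = None if theta is None else data.T @ theta
    if not np.all(np.isfinite(offset)) or (tau is not None and not np.all(np.isfinite(tau))):
        raise FloatingPointError("non-finite linear predictor")

    b0 = None if mode_cache is None else mode_cache.get("modes")
    mode, curv = _find_modes(data, model, offset, tau, a, sigma, b0=b0)
    if mode_cache is not None:
        mode_cache["modes"] = mode
    s_h = 1.0 / np.sqrt(curv)

    x_q, w_q = np.polynomial.hermite.hermgauss(n_quad)
    b_nodes = mode[None, :] + np.sqrt(2.0) * s_h[None, :] * x_q[:, None]  # (Q, H)
    z_nodes = (b_nodes - a) / sigma

    kappa = b_nodes[:, data.hospital_index] + offset[None, :]  # (Q, N)
    ll, dk, dt, _ = _row_terms(model, kappa, tau, data.y, derivs=want_grad)
    logA = data.group_sum(ll)  # (Q, H)

    P = np.polynomial.polynomial.polyval(z_nodes, xi)
    log_core = (
        np.log(w_q)[:, None]
        + x_q[:, None] ** 2
        + logA
        - 0.5 * z_nodes**2
        - 0.5 * _LOG_2PI
        - log_sigma
        + np.log(np.sqrt(2.0) * s_h)[None, :]
    )
    M = np.max(log_core, axis=0)
    r = np.exp(log_core - M[None, :])  # bounded by 1
    P2 = P**2
    denom = np.sum(r * P2, axis=0)
    denom = np.maximum(denom, 1e-300)
    loglik_h = M + np.log(denom)
    total = float(np.sum(loglik_h))
    if not want_grad:
        return total, None

    # ---- score: posterior expectation over the same nodes ----------------
    omega = (r * P2) / denom[None, :]  # (Q, H), rows sum to 1 per hospital
    omega_rows = omega[:, data.hospital_index]  # (Q, N)

    wrow_k = np.einsum("qn,qn->n", omega_rows, dk)
    g_beta = data.X.T @ wrow_k
    # gamma enters through the per-hospital spline value
    per_h_dk = np.einsum("qh,qh->h", omega, data.group_sum(dk))
    g_gamma = basis_design.T @ per_h_dk

    if K > 0:
        dP = np.polynomial.polynomial.polyval(
            z_nodes, xi[1:] * np.arange(1, K + 1)
        )
    else:
        dP = np.zeros_like(z_nodes)
    ru = r / denom[None, :]
    g_a = float(np.sum(ru * (P2 * z_nodes - 2.0 * P * dP)) / sigma)
    g_s = float(np.sum(ru * (P2 * (z_nodes**2 - 1.0) - 2.0 * P * dP * z_nodes)))

    g_angles = np.zeros(K)
    if K > 0:
        # dP/dphi_m = polyval(z, dxi[:, m])
        for m in range(K):
            dPm = np.polynomial.polynomial.polyval(z_nodes, dxi[:, m])
            g_angles[m] = np.sum(ru * 2.0 * P * dPm)

    if theta is not None:
        wrow_t = np.einsum("qn,qn->n", omega_rows, dt)
        g_theta = data.T.T @ wrow_t
    else:
        g_theta = np.zeros(0)

    grad = np.concatenate([g_beta, g_gamma, [g_a, g_s], g_angles, g_theta])
    return total, grad


# --------------------------------------------------------------------------
# packing
# --------------------------------------------------------------------------

def _layout(p_x, m_n, K, p_t):
    return {"p_x": p_x, "m_n": m_n, "K": K, "p_t": p_t}


def _pack(beta, gamma, a, log_sigma, angles, theta):
    parts = [beta, gamma, [a, log_sigma], angles]
    if theta is not None:
        parts.append(theta)
    return np.concatenate([np.atleast_1d(np.asarray(p, dtype=float)) for p in parts])


def _unpack(x, layout):
    p_x, m_n, K, p_t = layout["p_x"], layout["m_n"], layout["K"], layout["p_t"]
    i = 0
    beta = x[i : i + p_x]; i += p_x
    gamma = x[i : i + m_n]; i += m_n
    a = x[i]; log_sigma = x[i + 1]; i += 2
    angles = x[i : i + K]; i += K
    theta = x[i : i + p_t] if p_t else None
    return beta, gamma, a, log_sigma, angles, theta


def _params_from_vec(x, layout):
    beta, gamma, a, log_sigma, angles, theta = _unpack(x, layout)
    return ModelParams(
        beta=beta.copy(),
        gamma=gamma.copy(),
        snp=SNPDensityParams(K=layout["K"], a=float(a), sigma=float(np.exp(log_sigma)), angles=angles.copy()),
        theta=None if theta is None else theta.copy(),
    )


def _vec_from_params(params: ModelParams):
    return _pack(
        params.beta,
        params.gamma,
        params.snp.a,
        np.log(params.snp.sigma),
        params.snp.angles,
        params.theta,
    )


# --------------------------------------------------------------------------
# public likelihood evaluators
# --------------------------------------------------------------------------

def _loglik(data, params: ModelParams, basis: SplineBasisSpec, n_quad, model):
    if n_quad < 3:
        raise ValueError("n_quad must be >= 3")
    if model == "zib" and data.T is None:
        raise ValueError("zero-inflated model requires T covariates")
    layout = _layout(
        len(np.atleast_1d(params.beta)),
        len(np.atleast_1d(params.gamma)),
        params.snp.K,
        0 if params.theta is None else len(np.atleast_1d(params.theta)),
    )
    design = basis.design(data.V)
    val, _ = _marginal(data, model, _vec_from_params(params), layout, design, n_quad)
    return val


def hcam_marginal_loglik(data: HospitalDataset, params: ModelParams,
                         basis: SplineBasisSpec, n_quad: int = 21) -> float:
    """Marginal log-likelihood of the HCAM (no zero-inflation layer)."""
    return _loglik(data, params, basis, n_quad, "hcam")


def zib_marginal_loglik(data: HospitalDataset, params: ModelParams,
                        basis: SplineBasisSpec, n_quad: int = 21) -> float:
    """Marginal log-likelihood of the ZI-HCAM (requires ``data.T`` and theta)."""
    return _loglik(data, params, basis, n_quad, "zib")


# --------------------------------------------------------------------------
# fitting
# --------------------------------------------------------------------------

def _logistic_warm_start(data, design, model):
    """No-random-effect logistic fit for starting values (intercept -> a)."""
    from sklearn.linear_model import LogisticRegression

    Z = np.hstack([data.X, design[data.hospital_index]])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        lr = LogisticRegression(penalty=None, max_iter=300)
        lr.fit(Z, data.y)
    beta = lr.coef_[0, : data.X.shape[1]]
    gamma = lr.coef_[0, data.X.shape[1] :]
    a = float(lr.intercept_[0])
    # theta = 0 starts the at-risk probability at 1/2 everywhere: the
    # initial likelihood is lower than the plain Bernoulli one but the
    # inflation score is far from its saturated (vanishing-gradient) regime
    theta = np.zeros(data.T.shape[1]) if model == "zib" else None
    return beta, gamma, a, theta


def fit(
    data: HospitalDataset,
    model: str = "hcam",
    d: int = 3,
    q: int = 3,
    K_grid=(0, 1, 2, 3),
    n_quad: int = 21,
    knot_placement: str = "uniform",
    selection: str = "bic",
    max_iter: int = 500,
    gtol: float = 1e-5,
    ftol: float = 1e-8,
    verbose: bool = False,
) -> FitResult:
    """Fit the model for every K in ``K_grid`` and select by information
    criterion.

    The K grid is traversed in ascending order; K=0 is warm-started from a
    no-random-effect logistic fit (its intercept seeds the location ``a``,
    scale starts at 1), and each larger K is warm-started from the previous
    solution with the polynomial padded by a zero leading coefficient (plus
    perturbed restarts; see ``_start_points``).  ``selection`` is "bic"
    (default) or "aic"; ties resolve to the smaller K.  BIC's ``log N``
    penalty is appropriate at large scale but can exceed any attainable
    likelihood gain in small studies, where "aic" keeps the comparison
    informative.  Hospitals with no outcome variation trigger a warning but
    are kept.
    """
    if selection not in ("bic", "aic"):
        raise ValueError("selection must be 'bic' or 'aic'")
    if model not in ("hcam", "zib"):
        raise ValueError(f"unknown model {model!r}")
    if model == "zib" and data.T is None:
        raise ValueError("zero-inflated model requires T covariates")
    K_grid = sorted(int(k) for k in K_grid)

    event_h = data.group_sum(data.y)
    flat = (event_h == 0) | (event_h == data.n_h)
    if flat.any():
        warnings.warn(
            f"{int(flat.sum())} hospital(s) have no outcome variation; their "
            "random effects are weakly identified",
            stacklevel=2,
        )

    basis, design = build_basis(data.V, d=d, q=q, knot_placement=knot_placement)
    m_n = basis.n_basis
    p_x = data.X.shape[1]
    p_t = 0 if model == "hcam" else data.T.shape[1]

    beta0, gamma0, a0, theta0 = _logistic_warm_start(data, design, model)
    prev = _pack(beta0, gamma0, a0, 0.0, np.zeros(0), theta0)
    prev_K = 0

    per_k: dict[int, FitResult] = {}
    k_table = []
    for K in K_grid:
        layout = _layout(p_x, m_n, K, p_t)
        cache: dict = {}

        def nll(x, layout=layout, cache=cache):
            val, grad = _marginal(data, model, x, layout, design, n_quad,
                                  mode_cache=cache, want_grad=True)
            return -val, -grad

        bounds = (
            [(None, None)] * (p_x + m_n)
            + [(None, None), (-7.0, 7.0)]
            + [(-np.pi / 2 + 1e-6, np.pi / 2)] * K
            + [(None, None)] * p_t
        )
        # The continuation start (previous optimal polynomial padded with a
        # zero coefficient) preserves the nested-likelihood path but is an
        # exact stationary point when the previous fit was the Gaussian ML
        # solution: degree <= 2 polynomial perturbations are spanned by the
        # location/scale scores there.  Perturbed starts on the new angle(s)
        # let the optimizer escape that saddle; the best of all starts wins.
        res = None
        for x0 in _start_points(prev, prev_K, K, layout, p_x, m_n, p_t):
            cand = minimize(
                nll, x0, jac=True, method="L-BFGS-B", bounds=bounds,
                options={"maxiter": max_iter, "ftol": ftol, "gtol": gtol,
                         "maxls": 40},
            )
            if res is None or cand.fun < res.fun:
                res = cand
        ll = -float(res.fun)
        params = _params_from_vec(res.x, layout)
        # centered basis columns sum to zero row-wise, so the spline block
        # spans q + d dimensions: one gamma coordinate is redundant
        p_free = params.n_free - 1
        aic = -2 * ll + 2 * p_free
        bic = -2 * ll + p_free * np.log(data.N)
        mean_b, var_b = snp_moments(params.snp)
        b_modes = empirical_bayes_effects(data, params, basis, model=model)
        fit_k = FitResult(
            model=model, params=params, basis=basis,
            hospital_ids=data.unique_ids.copy(), V=data.V.copy(),
            loglik=ll, aic=aic, bic=bic, n_quad_points=n_quad,
            converged=bool(res.success), iterations=int(res.nit),
            random_effect_mean=mean_b, random_effect_variance=var_b,
            b_modes=b_modes, n_free=p_free,
        )
        per_k[K] = fit_k
        k_table.append({"K": K, "loglik": ll, "aic": aic, "bic": bic,
                        "converged": bool(res.success), "iterations": int(res.nit)})
        if verbose:
            print(f"K={K}: loglik={ll:.4f} bic={bic:.4f} converged={res.success}")
        if not res.success:
            warnings.warn(f"K={K} fit did not converge: {res.message}", stacklevel=2)
        prev, prev_K = res.x, K

    crit = (lambda r: r.bic) if selection == "bic" else (lambda r: r.aic)
    best_K = min(per_k, key=lambda k: (round(crit(per_k[k]), 9), k))
    selected = per_k[best_K]
    selected.k_table = k_table
    selected.per_k = per_k
    return selected


def _start_points(prev, prev_K, K, layout, p_x, m_n, p_t):
    """Starting vectors for degree K from the previous-degree solution.

    The first start continues the previous optimal polynomial exactly
    (padded with zero coefficients; the moment matrices are nested so it
    stays on the constraint surface).  The remaining starts perturb the
    newly introduced angle(s) in both directions to escape the stationary
    point that the continuation start sits on whenever the previous solution
    is the Gaussian ML fit.
    """
    beta, gamma, a, log_sigma, angles_prev, theta = _unpack(
        prev, _layout(p_x, m_n, prev_K, p_t)
    )
    if K == prev_K:
        return [_pack(beta, gamma, a, log_sigma, angles_prev, theta)]

    from .snp import angles_to_coefficients

    xi_prev = angles_to_coefficients(angles_prev)
    xi_pad = np.concatenate([xi_prev, np.zeros(K - prev_K)])
    cont = np.clip(coefficients_to_angles(xi_pad), -np.pi / 2 + 1e-6, np.pi / 2)
    starts = [_pack(beta, gamma, a, log_sigma, cont, theta)]
    for delta in (0.5, -0.5):
        # perturb every angle: the saddle affects the whole low-degree span
        pert = np.clip(cont + delta, -np.pi / 2 + 1e-6, np.pi / 2)
        starts.append(_pack(beta, gamma, a, log_sigma, pert, theta))
    if K >= 2:
        alt = np.clip(cont + 0.5 * (-1.0) ** np.arange(K), -np.pi / 2 + 1e-6, np.pi / 2)
        starts.append(_pack(beta, gamma, a, log_sigma, alt, theta))
    return starts


# --------------------------------------------------------------------------
# empirical-Bayes random effects and prediction
# --------------------------------------------------------------------------

def empirical_bayes_effects(
    data: HospitalDataset,
    params: ModelParams,
    basis: SplineBasisSpec,
    model: str = "hcam",
    method: str = "mode",
    n_quad: int = 41,
) -> np.ndarray:
    """Per-hospital posterior summary of ``b_h`` under the fitted model.

    ``method="mode"`` maximizes the posterior density (grid search over
    ``a +- 8 sigma`` with two local refinement passes; the SNP polynomial can
    make the posterior multimodal, so a gradient method alone is unsafe).
    ``method="mean"`` integrates with adaptive quadrature instead.
    """
    snp = params.snp
    offset = data.X @ params.beta + (basis.design(data.V) @ params.gamma)[data.hospital_index]
    tau = None if params.theta is None else data.T @ params.theta
    mdl = "zib" if (model == "zib" and params.theta is not None) else "hcam"

    def log_post(b_grid):
        # b_grid: (G, H) candidate effects per hospital
        kappa = b_grid[:, data.hospital_index] + offset[None, :]
        ll = _row_terms(mdl, kappa, tau, data.y)[0]
        z = (b_grid - snp.a) / snp.sigma
        P2 = snp.polynomial(z) ** 2
        return data.group_sum(ll) + np.log(P2 + 1e-300) - 0.5 * z**2

    if method == "mean":
        mode, curv = _find_modes(data, mdl, offset, tau, snp.a, snp.sigma)
        s_h = 1.0 / np.sqrt(curv)
        x_q, w_q = np.polynomial.hermite.hermgauss(n_quad)
        b_nodes = mode[None, :] + np.sqrt(2.0) * s_h[None, :] * x_q[:, None]
        lp = log_post(b_nodes) + x_q[:, None] ** 2 + np.log(w_q)[:, None]
        M = np.max(lp, axis=0)
        w = np.exp(lp - M[None, :])
        return np.sum(w * b_nodes, axis=0) / np.sum(w, axis=0)

    lo, width = snp.a - 8 * snp.sigma, 16 * snp.sigma
    grid = lo + width * np.linspace(0, 1, 401)[:, None] * np.ones(data.H)[None, :]
    best = grid[np.argmax(log_post(grid), axis=0), np.arange(data.H)]
    step = width / 400
    for _ in range(2):
        local = best[None, :] + step * np.linspace(-1, 1, 21)[:, None]
        best = local[np.argmax(log_post(local), axis=0), np.arange(data.H)]
        step = step / 10
    return best


def predict_mortality(result: FitResult, X, T=None, hospital=0) -> np.ndarray:
    """Per-row predicted mortality probability at a given hospital.

    ``hospital`` is either an index into the fitted hospitals (its
    empirical-Bayes effect mode and attribute are used) or a float giving a
    random-effect value directly (then the spline term uses that same
    hospital index 0 convention is *not* applied; pass an index for fitted
    hospitals).  For the zero-inflated model the at-risk probability is
    multiplied by ``expit(T theta)``.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if isinstance(hospital, (int, np.integer)):
        b = result.b_modes[hospital]
        fv = float(result.f_values(result.V[hospital : hospital + 1])[0])
    else:
        b = float(hospital)
        fv = 0.0
    pi = expit(b + fv + X @ result.params.beta)
    if result.model == "zib":
        if T is None:
            raise ValueError("zero-inflated prediction requires T covariates")
        T = np.atleast_2d(np.asarray(T, dtype=float))
        return pi * expit(T @ result.params.theta)
    return pi
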