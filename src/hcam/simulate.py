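"""Synthetic hospital-compare data generators and evaluation metrics.

The generators reproduce the simulation designs used to study the models:

* scenario A — vary the random-effect distribution over seven shapes
  (normal, uniform, exponential, log-normal, symmetric and asymmetric
  normal mixtures, two-point discrete), each standardized to mean 0 and
  variance 1, with the fixed effect ``f4(V) = exp(-2V) sin(6V) - 0.5748``;
* scenario B — vary the fixed-effect function over ``f1..f4`` with a
  bimodal random effect ``0.7 N(-1.5, 0.7^2) + 0.3 N(2, 0.7^2)``;
* scenario ZIB — a two-status generator: a latent at-risk indicator ``S``
  with ``logit P(S=1) = theta * X*`` (``X* ~ N(1, 1.5^2)``) gates a
  Bernoulli mortality outcome, producing excess zeros.

Patient covariates are ``X ~ N(0, I_3)`` with effects ``beta = (3, 0.5, -5)``
and the hospital attribute is ``V ~ Uniform(-1, 1)``.  All randomness flows
from one seed through named substreams so each component is independently
reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.integrate import quad
from scipy.optimize import brentq
from scipy.special import expit

from .data import HospitalDataset
from .model import FitResult, fit

__all__ = [
    "ScenarioSpec",
    "MetricsReport",
    "true_fixed_effect",
    "fixed_effect_centering_mean",
    "lognormal_unit_variance_params",
    "symmetric_mixture_mean",
    "sample_random_effect",
    "generate",
    "split_train_test",
    "metrics",
    "delong_auc_ci",
    "classification_metrics",
    "replicate",
]

BETA_DEFAULT = np.array([3.0, 0.5, -5.0])

# ---------------------------------------------------------------------------
# fixed-effect functions (centering constants as printed in the study design)
# ---------------------------------------------------------------------------

_F_CENTER = {2: 0.5833, 4: 0.5748}


def true_fixed_effect(fid: int, v) -> np.ndarray:
    """The four benchmark fixed-effect functions of the simulation design."""
    v = np.asarray(v, dtype=float)
    if fid == 0:  # no hospital fixed effect (null design for testing)
        return np.zeros_like(v)
    if fid == 1:
        return 2.0 * v
    if fid == 2:
        return (v - 0.5) ** 2 - _F_CENTER[2]
    if fid == 3:
        return v * np.cos(3.0 * v) ** 3
    if fid == 4:
        return np.exp(-2.0 * v) * np.sin(6.0 * v) - _F_CENTER[4]
    raise ValueError(f"fixed-effect id must be 1..4, got {fid!r}")


def fixed_effect_centering_mean(fid: int) -> float:
    """Mean of the *uncentered* f2 or f4 shape under V ~ Uniform(-1, 1).

    This is the constant subtracted in the function definitions so that
    E[f(V)] = 0; recomputed here by quadrature.
    """
    if fid == 2:
        g = lambda v: (v - 0.5) ** 2
    elif fid == 4:
        g = lambda v: np.exp(-2.0 * v) * np.sin(6.0 * v)
    else:
        raise ValueError("centering constants exist for fids 2 and 4")
    val, _ = quad(g, -1.0, 1.0, limit=200)
    return 0.5 * val


def lognormal_unit_variance_params() -> tuple[float, float]:
    """(sigma, shift) standardizing LogN(0, sigma) to mean 0, variance 1.

    sigma solves (e^{sigma^2} - 1) e^{sigma^2} = 1 (so the variance is one)
    and the shift is the lognormal mean e^{sigma^2 / 2}.
    """
    g = lambda s: (np.exp(s**2) - 1.0) * np.exp(s**2) - 1.0
    sigma = brentq(g, 0.1, 2.0, xtol=1e-12)
    return float(sigma), float(np.exp(sigma**2 / 2.0))


def symmetric_mixture_mean(component_sd: float = 0.28) -> float:
    """Component mean +-m making 0.5 N(-m, s^2) + 0.5 N(m, s^2) unit variance."""
    return float(np.sqrt(1.0 - component_sd**2))


# ---------------------------------------------------------------------------
# random-effect distributions
# ---------------------------------------------------------------------------

_DIST_NAMES = {
    1: "normal", 2: "uniform", 3: "exponential", 4: "lognormal",
    5: "symmetric_mixture", 6: "asymmetric_mixture", 7: "discrete",
}
RANDOM_EFFECT_DISTRIBUTIONS = tuple(_DIST_NAMES.values()) + ("bimodal_raw", "bimodal_std")


def _mixture(rng, n, weights, means, sds):
    comp = rng.choice(len(weights), size=n, p=weights)
    return rng.normal(np.asarray(means)[comp], np.asarray(sds)[comp])


def sample_random_effect(dist, H: int, seed=None) -> np.ndarray:
    """Draw H hospital effects from one of the benchmark distributions.

    ``dist`` may be an integer id 1-7 or a name; ``"bimodal_raw"`` is the
    unstandardized mixture 0.7 N(-1.5, 0.7^2) + 0.3 N(2, 0.7^2) (mean -0.45,
    variance 3.0625) and ``"bimodal_std"`` its mean-0/variance-1 rescaling.
    """
    name = _DIST_NAMES.get(dist, dist)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if name == "zero":  # degenerate: no hospital heterogeneity (testing)
        return np.zeros(H)
    if name == "normal":
        return rng.standard_normal(H)
    if name == "uniform":
        return rng.uniform(-np.sqrt(3.0), np.sqrt(3.0), H)
    if name == "exponential":
        return rng.exponential(1.0, H) - 1.0
    if name == "lognormal":
        return rng.lognormal(0.0, 0.6937, H) - 1.2720
    if name == "symmetric_mixture":
        return _mixture(rng, H, [0.5, 0.5], [-0.96, 0.96], [0.28, 0.28])
    if name == "asymmetric_mixture":
        return _mixture(rng, H, [2 / 3, 1 / 3], [-2 / 3, 4 / 3], [1 / 3, 1 / 3])
    if name == "discrete":
        return rng.choice([-1.0, 1.0], size=H)
    if name == "bimodal_raw":
        return _mixture(rng, H, [0.7, 0.3], [-1.5, 2.0], [0.7, 0.7])
    if name == "bimodal_std":
        raw = _mixture(rng, H, [0.7, 0.3], [-1.5, 2.0], [0.7, 0.7])
        return (raw + 0.45) / 1.75
    raise ValueError(f"unknown random-effect distribution {dist!r}")


# ---------------------------------------------------------------------------
# scenario generator
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScenarioSpec:
    """Generative design for one synthetic dataset.

    ``scenario`` is "A" (random-effect study), "B" (fixed-effect study) or
    "ZIB" (two-status zero-inflated outcomes).  ``theta`` only applies to
    ZIB; ``share_s_covariate`` makes the N(1, 1.5^2) at-risk covariate also
    replace the first mortality covariate (the alternative reading of the
    two-status design; by default it is a separate covariate that appears
    only in the at-risk model and in ``T``).
    """

    scenario: str = "A"
    H: int = 500
    n_h: int = 50
    re_dist: str | int | None = None  # None = scenario default
    f_id: int = 4
    beta: np.ndarray = field(default_factory=lambda: BETA_DEFAULT.copy())
    theta: float | None = -2.0  # None = saturated at-risk probability
    seed: int = 0
    share_s_covariate: bool = False

    def __post_init__(self):
        if self.scenario not in ("A", "B", "ZIB"):
            raise ValueError("scenario must be 'A', 'B' or 'ZIB'")
        object.__setattr__(self, "beta", np.asarray(self.beta, dtype=float))


def generate(spec: ScenarioSpec) -> tuple[HospitalDataset, dict]:
    """Generate one dataset plus a hidden-truth record.

    Returns ``(data, truth)`` where ``truth`` holds the drawn hospital
    effects ``b``, the true fixed-effect values ``f``, the latent at-risk
    statuses ``S`` (ZIB only) and the generating parameters.
    """
    ss = np.random.SeedSequence(spec.seed)
    rng_b, rng_v, rng_x, rng_s, rng_y, rng_split = (
        np.random.default_rng(c) for c in ss.spawn(6)
    )
    H, n_h = spec.H, spec.n_h
    N = H * n_h

    dist = spec.re_dist
    if dist is None:
        # scenario defaults: A studies the normal baseline, B draws from the
        # raw bimodal mixture, ZIB from its standardized version
        dist = {"A": "normal", "B": "bimodal_raw", "ZIB": "bimodal_std"}[spec.scenario]
    b = sample_random_effect(dist, H, rng_b)
    V = rng_v.uniform(-1.0, 1.0, H)
    f_id = spec.f_id
    f_vals = true_fixed_effect(f_id, V)
    X = rng_x.normal(0.0, 1.0, (N, len(spec.beta)))

    hidx = np.repeat(np.arange(H), n_h)
    ids = np.array([f"h{i + 1:04d}" for i in hidx])

    S = None
    T = None
    if spec.scenario == "ZIB":
        x_star = rng_s.normal(1.0, 1.5, N)
        if spec.share_s_covariate:
            X[:, 0] = x_star
        # theta=None saturates the at-risk probability (rho ~ 1), which
        # reduces the two-status generator to the plain Bernoulli one
        rho = expit(30.0) if spec.theta is None else expit(spec.theta * x_star)
        S = (rng_s.random(N) < rho).astype(float)
        T = np.column_stack([np.ones(N), x_star])

    kappa = b[hidx] + f_vals[hidx] + X @ spec.beta
    pi = expit(kappa)
    Y = (rng_y.random(N) < pi).astype(float)
    if S is not None:
        Y = Y * S

    data = HospitalDataset(hospital_ids=ids, y=Y, X=X, V=V, T=T)
    truth = {
        "spec": spec,
        "b": b,
        "V": V,
        "f": f_vals,
        "f_id": f_id,
        "beta": spec.beta.copy(),
        "theta": spec.theta if spec.scenario == "ZIB" else None,
        "S": S,
        "split_rng": rng_split,
    }
    return data, truth


def split_train_test(data: HospitalDataset, rng=None) -> tuple[HospitalDataset, HospitalDataset]:
    """Random half split within every cluster (train gets the extra row)."""
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    train_mask = np.zeros(data.N, dtype=bool)
    for s, e in zip(data.group_starts, np.append(data.group_starts[1:], data.N)):
        rows = np.arange(s, e)
        rng.shuffle(rows)
        train_mask[rows[: (len(rows) + 1) // 2]] = True
    return data.subset(train_mask), data.subset(~train_mask)


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

@dataclass
class MetricsReport:
    ise: float
    rd: float
    eb_hat: float
    varb_hat: float
    auc: float | None = None
    auc_ci: tuple[float, float] | None = None
    accuracy: float | None = None
    f1: float | None = None
    ppv: float | None = None
    threshold: float | None = None

    def to_dict(self) -> dict:
        d = {"ise": self.ise, "rd": self.rd, "eb_hat": self.eb_hat,
             "varb_hat": self.varb_hat, "auc": self.auc,
             "accuracy": self.accuracy, "f1": self.f1, "ppv": self.ppv,
             "threshold": self.threshold}
        if self.auc_ci is not None:
            d["auc_lo"], d["auc_hi"] = self.auc_ci
        return d


def delong_auc_ci(y_true, scores, level: float = 0.95):
    """AUC with a DeLong covariance confidence interval.

    Returns ``(auc, lo, hi)``.  The AUC estimate is the usual Mann-Whitney
    statistic computed from midranks; its variance combines the structural
    components of the positive and negative score placements.
    """
    from scipy.stats import norm as _norm, rankdata

    y = np.asarray(y_true).astype(bool)
    s = np.asarray(scores, dtype=float)
    pos, neg = s[y], s[~y]
    m, n = len(pos), len(neg)
    if m == 0 or n == 0:
        raise ValueError("need both positive and negative labels for AUC")
    all_r = rankdata(np.concatenate([pos, neg]))
    r_pos = rankdata(pos)
    r_neg = rankdata(neg)
    auc = (np.sum(all_r[:m]) - m * (m + 1) / 2) / (m * n)
    v01 = (all_r[:m] - r_pos) / n  # placement of each positive among negatives
    v10 = 1.0 - (all_r[m:] - r_neg) / m
    var = np.var(v01, ddof=1) / m + np.var(v10, ddof=1) / n
    z = _norm.ppf(0.5 + level / 2)
    half = z * np.sqrt(max(var, 0.0))
    return float(auc), float(max(auc - half, 0.0)), float(min(auc + half, 1.0))


def classification_metrics(y_true, scores, threshold: float) -> dict:
    """Accuracy, F1 and PPV of the rule score >= threshold."""
    y = np.asarray(y_true).astype(bool)
    pred = np.asarray(scores, dtype=float) >= threshold
    tp = np.sum(pred & y)
    fp = np.sum(pred & ~y)
    fn = np.sum(~pred & y)
    tn = np.sum(~pred & ~y)
    ppv = tp / (tp + fp) if tp + fp else np.nan
    rec = tp / (tp + fn) if tp + fn else np.nan
    f1 = 2 * ppv * rec / (ppv + rec) if (ppv + rec) else np.nan
    acc = (tp + tn) / len(y)
    return {"accuracy": float(acc), "f1": float(f1), "ppv": float(ppv)}


def _test_scores(result: FitResult, test: HospitalDataset) -> np.ndarray:
    """Predicted mortality probability for every test row, matching test
    hospitals to fitted hospitals by identifier."""
    pos = {h: i for i, h in enumerate(result.hospital_ids)}
    fit_idx = np.array([pos[h] for h in test.unique_ids])
    b = result.b_modes[fit_idx][test.hospital_index]
    fv = result.f_values(test.V)[test.hospital_index]
    pi = expit(b + fv + test.X @ result.params.beta)
    if result.model == "zib":
        pi = pi * expit(test.T @ result.params.theta)
    return pi


def metrics(truth: dict, result: FitResult, test: HospitalDataset | None = None,
            threshold: float | None = None) -> MetricsReport:
    """Evaluate a fit against the generating truth (and held-out data).

    ISE averages the squared error of the fitted fixed-effect curve over the
    hospital attributes; RD is the relative Euclidean error of beta; the
    classification metrics use the training observed rate as threshold
    unless one is given.
    """
    f_hat = result.f_values(truth["V"])
    ise = float(np.mean((f_hat - truth["f"]) ** 2))
    beta = truth["beta"]
    rd = float(np.linalg.norm(result.params.beta - beta) / np.linalg.norm(beta))
    rep = MetricsReport(
        ise=ise, rd=rd,
        eb_hat=result.random_effect_mean,
        varb_hat=result.random_effect_variance,
    )
    if test is not None:
        scores = _test_scores(result, test)
        rep.auc, lo, hi = delong_auc_ci(test.y, scores)
        rep.auc_ci = (lo, hi)
        rep.threshold = float(threshold) if threshold is not None else float(np.mean(test.y))
        cm = classification_metrics(test.y, scores, rep.threshold)
        rep.accuracy, rep.f1, rep.ppv = cm["accuracy"], cm["f1"], cm["ppv"]
    return rep


# ---------------------------------------------------------------------------
# replication harness
# ---------------------------------------------------------------------------

def replicate(
    base_spec: ScenarioSpec,
    n_replicates: int,
    models=("hcam",),
    K_grid=(0, 1, 2),
    d: int = 3,
    q: int = 3,
    n_quad: int = 21,
    selection: str = "aic",
    split: bool = False,
    seed: int | None = None,
) -> pd.DataFrame:
    """Run generate -> fit -> metrics over seeded replicates.

    Each replicate re-seeds the generator from ``seed + r`` (or
    ``base_spec.seed + r``); when ``split`` is true the data are halved
    within clusters, models are fitted on the training half and the
    prediction metrics are computed on the held-out half.  K is selected by
    AIC by default: replicate grids are typically run at reduced scale,
    where the BIC penalty exceeds any attainable likelihood gain and would
    collapse every comparison onto the Gaussian fit.
    """
    rows = []
    seed0 = base_spec.seed if seed is None else seed
    for r in range(n_replicates):
        spec = replace(base_spec, seed=seed0 + r)
        data, truth = generate(spec)
        if split:
            train, test = split_train_test(data, truth["split_rng"])
        else:
            train, test = data, None
        thr = float(np.mean(train.y))
        for model in models:
            res = fit(train, model=model, d=d, q=q, K_grid=K_grid,
                      n_quad=n_quad, selection=selection)
            rep = metrics(truth, res, test=test, threshold=thr)
            row = {"replicate": r, "seed": spec.seed, "model": model,
                   "scenario": spec.scenario, "re_dist": str(spec.re_dist),
                   "f_id": truth["f_id"], "K_selected": res.params.snp.K,
                   "loglik": res.loglik, "bic": res.bic,
                   "converged": res.converged}
            row.update(rep.to_dict())
            # forced-normal comparator is the K=0 entry of the same grid
            if 0 in res.per_k:
                k0 = res.per_k[0]
                row["eb_hat_normal"] = k0.random_effect_mean
                row["varb_hat_normal"] = k0.random_effect_variance
            rows.append(row)
    return pd.DataFrame(rows)
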