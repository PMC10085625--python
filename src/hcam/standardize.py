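"""Risk-standardized mortality rates, hospital ranks and bootstrap intervals.

Given a fitted model, each hospital ``h`` gets

* ``P_h`` — the model-average mortality of its own patients,
* ``E_h`` — the (possibly volume-weighted) expected mortality had those same
  patients been treated across all hospitals,
* ``P_h^IS = (P_h / E_h) * OR`` — the indirectly standardized rate, scaled
  by the overall observed rate ``OR``,
* ``P_h^DS`` — the directly standardized rate: hospital ``h``'s average
  predicted mortality over the covariates of *every* patient in the data.

Ranks are ascending in the rate (rank 1 = lowest = best), quartile labels
run 1 (best) to 4 (worst), and uncertainty comes from subsampling patient
cases without replacement and recomputing the rates under the fixed fitted
parameters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

from .data import HospitalDataset
from .model import FitResult

__all__ = [
    "StandardizedRates",
    "observed_rates",
    "prediction_matrix",
    "hospital_risk_P",
    "expected_risk_E",
    "indirect_rate",
    "direct_rate",
    "rank_and_quartiles",
    "bootstrap_ci",
    "standardized_rates",
]


@dataclass
class StandardizedRates:
    """Per-hospital standardized-rate table plus global quantities."""

    hospital_ids: np.ndarray
    n_h: np.ndarray
    observed: np.ndarray  # OR_h
    P: np.ndarray
    E: np.ndarray
    indirect: np.ndarray  # P^IS_h
    direct: np.ndarray  # P^DS_h
    rank: np.ndarray  # of the direct rate; 1 = best (lowest)
    quartile: np.ndarray  # 1 (best) .. 4 (worst)
    overall_rate: float  # OR
    weights: np.ndarray
    ci_low: np.ndarray | None = None
    ci_high: np.ndarray | None = None
    indirect_ci_low: np.ndarray | None = None
    indirect_ci_high: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "hospital_id": self.hospital_ids,
                "n_h": self.n_h,
                "OR_h": self.observed,
                "P_h": self.P,
                "E_h": self.E,
                "P_IS": self.indirect,
                "P_DS": self.direct,
                "rank": self.rank,
                "quartile": self.quartile,
            }
        )
        if self.ci_low is not None:
            df["ci_low"] = self.ci_low
            df["ci_high"] = self.ci_high
        return df


def observed_rates(data: HospitalDataset) -> tuple[float, np.ndarray]:
    """Overall and per-hospital observed event rates (exact sample means)."""
    or_h = data.group_sum(data.y) / data.n_h
    return float(np.mean(data.y)), or_h


def prediction_matrix(result: FitResult, data: HospitalDataset) -> np.ndarray:
    """N x H matrix of predicted mortality: row j, column script-H gives the
    probability for patient j's covariates had they been treated at hospital
    script-H (its empirical-Bayes effect and attribute).  For the
    zero-inflated model the patient's own at-risk probability multiplies
    every column.  Columns follow the dataset's hospital order; hospitals
    are matched to the fit by identifier."""
    pos = {h: i for i, h in enumerate(result.hospital_ids)}
    try:
        align = np.array([pos[h] for h in data.unique_ids])
    except KeyError as err:
        raise ValueError(f"hospital {err.args[0]!r} was not in the fitted model") from None
    b = result.b_modes[align]
    fv = result.f_values(result.V[align])
    kappa = data.X @ result.params.beta  # (N,)
    M = expit(kappa[:, None] + (b + fv)[None, :])
    if result.model == "zib":
        if data.T is None:
            raise ValueError("zero-inflated standardization requires T covariates")
        M = M * expit(data.T @ result.params.theta)[:, None]
    return M


def hospital_risk_P(result: FitResult, data: HospitalDataset, M=None) -> np.ndarray:
    """P_h: average predicted mortality of hospital h's own patients."""
    M = prediction_matrix(result, data) if M is None else M
    own = M[np.arange(data.N), data.hospital_index]
    return data.group_sum(own) / data.n_h


def expected_risk_E(result: FitResult, data: HospitalDataset, weights="uniform",
                    M=None) -> np.ndarray:
    """E_h: expected mortality of h's patients under system-wide treatment.

    For each of hospital h's patients the predicted mortality is averaged
    over all hospitals with weights ``w`` (uniform = 1/H each; "volume"
    uses w_H = n_H / N), then averaged over the hospital's patients.
    """
    M = prediction_matrix(result, data) if M is None else M
    w = _resolve_weights(weights, data)
    per_patient = M @ w
    return data.group_sum(per_patient) / data.n_h


def _resolve_weights(weights, data: HospitalDataset) -> np.ndarray:
    if isinstance(weights, str):
        if weights == "uniform":
            return np.full(data.H, 1.0 / data.H)
        if weights == "volume":
            return data.n_h / data.N
        raise ValueError(f"unknown weights mode {weights!r}")
    w = np.asarray(weights, dtype=float).reshape(-1)
    if w.size != data.H:
        raise ValueError(f"weights have length {w.size}, expected H={data.H}")
    if abs(w.sum() - 1.0) > 1e-8:
        raise ValueError("weights must sum to 1")
    return w


def indirect_rate(P: np.ndarray, E: np.ndarray, overall: float) -> np.ndarray:
    """P^IS_h = (P_h / E_h) * OR; the ratio form may exceed 1 and is
    reported as-is."""
    return np.asarray(P) / np.asarray(E) * overall


def direct_rate(result: FitResult, data: HospitalDataset, M=None) -> np.ndarray:
    """P^DS_h: hospital h's average predicted mortality over all N patients."""
    M = prediction_matrix(result, data) if M is None else M
    return M.mean(axis=0)


def rank_and_quartiles(rates) -> tuple[np.ndarray, np.ndarray]:
    """Ascending ranks (1 = lowest rate = best) and quartile labels 1-4.

    Ties keep the hospitals' original (id) order; quartiles are by rank
    position so group sizes differ by at most one.
    """
    rates = np.asarray(rates, dtype=float)
    H = len(rates)
    order = np.argsort(rates, kind="stable")
    rank = np.empty(H, dtype=int)
    rank[order] = np.arange(1, H + 1)
    quartile = (rank - 1) * 4 // H + 1
    return rank, quartile


def bootstrap_ci(
    result: FitResult,
    data: HospitalDataset,
    B: int = 2000,
    m: int = 2000,
    level: float = 0.95,
    seed=None,
    weights="volume",
    statistic: str = "direct",
    replace: bool = False,
    refit: dict | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Percentile intervals for standardized rates by case resampling.

    Each of the ``B`` replicates draws ``m`` patient rows — *without*
    replacement by default (a subsampling scheme; ``replace=True`` gives a
    classical bootstrap) — keeps the fitted parameters fixed, and recomputes
    the requested standardized rate ("direct" or "indirect") on the
    resample.  ``refit`` may be a dict of :func:`hcam.model.fit` keyword
    arguments to re-estimate the model on every resample instead of reusing
    the fitted parameters; that is faithful bootstrap inference but costs B
    maximum-likelihood fits.  Hospitals absent from a resample contribute
    NaN to that replicate (the direct rate never drops out; P_h/E_h can).
    """
    if m > data.N and not replace:
        raise ValueError(f"cannot subsample m={m} from N={data.N} without replacement")
    rng = np.random.default_rng(seed)
    M = prediction_matrix(result, data)
    H = data.H
    stats = np.full((B, H), np.nan)
    alpha = (1.0 - level) / 2
    for b_i in range(B):
        rows = rng.choice(data.N, size=m, replace=replace)
        if refit is not None:
            from .model import fit as _fit

            sub = data.subset(rows)
            res_b = _fit(sub, model=result.model, **refit)
            Mb_full = prediction_matrix(res_b, sub)
            if statistic == "direct":
                stats[b_i, _align(result, sub)] = Mb_full.mean(axis=0)
                continue
            raise ValueError("refit intervals support the 'direct' statistic")
        Mb = M[rows]
        if statistic == "direct":
            stats[b_i] = Mb.mean(axis=0)
        elif statistic == "indirect":
            hidx = data.hospital_index[rows]
            counts = np.bincount(hidx, minlength=H).astype(float)
            present = counts > 0
            own = Mb[np.arange(m), hidx]
            P = np.bincount(hidx, weights=own, minlength=H)
            w = _resolve_weights(weights, data)
            per_patient = Mb @ w
            E = np.bincount(hidx, weights=per_patient, minlength=H)
            with np.errstate(invalid="ignore", divide="ignore"):
                P = np.where(present, P / counts, np.nan)
                E = np.where(present, E / counts, np.nan)
            overall = float(np.mean(data.y[rows]))
            stats[b_i] = indirect_rate(P, E, overall)
        else:
            raise ValueError(f"unknown statistic {statistic!r}")
    lo = np.nanquantile(stats, alpha, axis=0)
    hi = np.nanquantile(stats, 1.0 - alpha, axis=0)
    return lo, hi


def _align(result: FitResult, sub: HospitalDataset) -> np.ndarray:
    """Positions of a subsample's hospitals inside the original fit."""
    pos = {h: i for i, h in enumerate(result.hospital_ids)}
    return np.array([pos[h] for h in sub.unique_ids])


def standardized_rates(
    result: FitResult,
    data: HospitalDataset,
    weights="volume",
    bootstrap: dict | None = None,
) -> StandardizedRates:
    """Full standardized-rate table for a fitted model.

    ``bootstrap`` may be a dict of :func:`bootstrap_ci` keyword arguments
    (e.g. ``{"B": 2000, "m": 2000, "seed": 1}``) to attach percentile
    intervals for the direct rate.
    """
    M = prediction_matrix(result, data)
    overall, or_h = observed_rates(data)
    P = hospital_risk_P(result, data, M=M)
    E = expected_risk_E(result, data, weights=weights, M=M)
    pis = indirect_rate(P, E, overall)
    pds = direct_rate(result, data, M=M)
    rank, quartile = rank_and_quartiles(pds)
    out = StandardizedRates(
        hospital_ids=data.unique_ids.copy(),
        n_h=data.n_h,
        observed=or_h,
        P=P,
        E=E,
        indirect=pis,
        direct=pds,
        rank=rank,
        quartile=quartile,
        overall_rate=overall,
        weights=_resolve_weights(weights, data),
    )
    if bootstrap is not None:
        out.ci_low, out.ci_high = bootstrap_ci(
            result, data, weights=weights, statistic="direct", **bootstrap
        )
    return out
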