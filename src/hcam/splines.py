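"""Centered B-spline basis for the nonparametric hospital fixed effect.

The hospital attribute ``V`` (e.g. log volume) enters the linear predictor
through a smooth function ``f(V) = B(V)^T gamma``, approximated in a B-spline
basis of degree ``d`` with ``q`` interior knots, i.e. ``m_n = q + d + 1``
basis functions.  For identifiability the model requires ``E[f(V_h)] = 0``
over the hospital sample, so every basis column is centered by subtracting
its sample mean over the H hospitals used to build the basis.  Out-of-sample
attributes are affinely mapped to the build domain and clamped to its
boundary, avoiding polynomial extrapolation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import BSpline

__all__ = ["SplineBasisSpec", "build_basis", "evaluate_f"]


@dataclass(frozen=True)
class SplineBasisSpec:
    """Frozen description of a centered B-spline basis.

    ``knots`` is the full knot vector on the mapped [0, 1] scale with both
    boundary knots repeated ``degree + 1`` times; ``domain`` stores the
    original-attribute (min, max) used for the affine map; and
    ``centering_offsets`` holds the per-column means over the build sample of
    hospitals, subtracted to give mean-zero columns.
    """

    degree: int
    q: int
    knots: np.ndarray
    domain: tuple[float, float]
    centering_offsets: np.ndarray

    @property
    def n_basis(self) -> int:
        """Number of basis functions m_n = q + d + 1."""
        return self.q + self.degree + 1

    def map01(self, v) -> np.ndarray:
        """Affine map of attribute values to [0, 1], clamped to the boundary."""
        lo, hi = self.domain
        u = (np.asarray(v, dtype=float) - lo) / (hi - lo)
        return np.clip(u, 0.0, 1.0)

    def raw_design(self, v) -> np.ndarray:
        """Uncentered basis matrix at attribute values ``v`` (original scale)."""
        u = self.map01(v)
        dm = BSpline.design_matrix(u, self.knots, self.degree, extrapolate=False)
        return np.asarray(dm.todense())

    def design(self, v) -> np.ndarray:
        """Centered basis matrix: raw basis minus the build-sample column means."""
        return self.raw_design(v) - self.centering_offsets

    def to_dict(self) -> dict:
        return {
            "degree": int(self.degree),
            "q": int(self.q),
            "knots": [float(t) for t in self.knots],
            "domain": [float(self.domain[0]), float(self.domain[1])],
            "centering_offsets": [float(x) for x in self.centering_offsets],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SplineBasisSpec":
        return cls(
            degree=d["degree"],
            q=d["q"],
            knots=np.asarray(d["knots"], dtype=float),
            domain=(d["domain"][0], d["domain"][1]),
            centering_offsets=np.asarray(d["centering_offsets"], dtype=float),
        )


def _knot_vector(degree: int, q: int, interior: np.ndarray) -> np.ndarray:
    return np.concatenate([np.zeros(degree + 1), interior, np.ones(degree + 1)])


def build_basis(
    hospital_attrs,
    d: int = 3,
    q: int = 3,
    knot_placement: str = "uniform",
) -> tuple[SplineBasisSpec, np.ndarray]:
    """Build the centered basis from the H observed hospital attributes.

    Parameters
    ----------
    hospital_attrs : one attribute value per hospital (original scale).
    d : spline degree (3 = cubic, the usual default).
    q : number of interior knots.
    knot_placement : "uniform" for equally spaced interior knots on the mapped
        [0, 1] scale, or "quantile" to place them at sample quantiles (useful
        for skewed attributes such as raw admission volume).

    Returns
    -------
    (spec, design) where ``design`` is the H x m_n centered basis matrix.
    """
    v = np.asarray(hospital_attrs, dtype=float).reshape(-1)
    if d < 0 or q < 0:
        raise ValueError("degree and interior-knot count must be non-negative")
    lo, hi = float(np.min(v)), float(np.max(v))
    if not hi > lo:
        raise ValueError("need at least 2 distinct hospital attribute values")
    m_n = q + d + 1
    if len(v) < m_n:
        warnings.warn(
            f"only {len(v)} hospitals for {m_n} basis functions; design is rank-deficient",
            stacklevel=2,
        )
    u = (v - lo) / (hi - lo)
    if knot_placement == "uniform":
        interior = np.linspace(0, 1, q + 2)[1:-1]
    elif knot_placement == "quantile":
        interior = np.quantile(u, np.linspace(0, 1, q + 2)[1:-1])
    else:
        raise ValueError(f"unknown knot placement {knot_placement!r}")
    knots = _knot_vector(d, q, interior)
    raw = np.asarray(BSpline.design_matrix(u, knots, d, extrapolate=False).todense())
    offsets = raw.mean(axis=0)
    spec = SplineBasisSpec(
        degree=d, q=q, knots=knots, domain=(lo, hi), centering_offsets=offsets
    )
    return spec, raw - offsets


def evaluate_f(spec: SplineBasisSpec, gamma, v) -> np.ndarray:
    """Evaluate the fitted fixed effect ``f(v) = B(v)^T gamma``.

    ``gamma`` must have length ``spec.n_basis``.  Values outside the build
    domain are clamped to the boundary.
    """
    gamma = np.asarray(gamma, dtype=float).reshape(-1)
    if gamma.size != spec.n_basis:
        raise ValueError(f"gamma has length {gamma.size}, expected {spec.n_basis}")
    return spec.design(v) @ gamma
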