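"""Non-linear progress-curve kinetics.

Product accumulation under slowly drifting catalytic activity follows

.. math::

   [P](t) = \\frac{v_0}{\\eta} (1 - e^{-\\eta t})

with initial velocity ``v0`` (uM/h) and non-linearity factor ``eta``
(1/h).  Positive eta describes a decelerating reaction (substrate
depletion, product inhibition, catalyst inactivation); negative eta an
accelerating one (catalyst activation during progress); eta -> 0
recovers the linear law ``v0 t``.  The model is fitted per condition by
bounded trust-region least squares with a multi-start over eta, and a
simple origin-constrained linear slope over the earliest points is
reported alongside for comparison.

Standard errors come from the Gauss-Newton curvature; on sparse 5-point
designs they are indicative rather than exact (see the methods note).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "ProgressCurve",
    "ProgressFit",
    "eval_progress",
    "fit_progress",
    "classify_nonlinearity",
]

_ETA_STARTS = (-0.05, 0.0, 0.02, 0.05, 0.1)
_ETA_BOUNDS = (-1.0, 1.0)


@dataclass(frozen=True)
class ProgressCurve:
    """Product time course for one condition."""

    times_h: np.ndarray
    product_uM: np.ndarray
    s0_uM: float
    condition_id: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.times_h, dtype=float)
        p = np.asarray(self.product_uM, dtype=float)
        if t.shape != p.shape or t.ndim != 1:
            raise ValueError("times and product must be matching 1-d arrays")
        if t[0] != 0 or np.any(np.diff(t) <= 0):
            raise ValueError("times must start at 0 and increase strictly")
        if np.any(p < -0.05 * self.s0_uM) or np.any(p > 1.05 * self.s0_uM):
            raise ValueError("product outside [0, s0] beyond 5% tolerance")
        object.__setattr__(self, "times_h", t)
        object.__setattr__(self, "product_uM", p)


@dataclass(frozen=True)
class ProgressFit:
    """Fitted (v0, eta) with uncertainties and the linear comparator."""

    v0: float
    eta: float
    v0_se: float
    eta_se: float
    rss: float
    linear_v0: float
    condition_id: str = ""
    eta_defined: bool = True


def _phi(x):
    """(1 - exp(-x))/x, series-protected near 0."""
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    small = np.abs(x) < 1e-8
    out[small] = 1.0 - x[small] / 2.0
    xs = x[~small]
    out[~small] = -np.expm1(-xs) / xs
    return out


def eval_progress(v0: float, eta: float, t) -> np.ndarray | float:
    """[P](t) = v0/eta (1 - e^(-eta t)), continuous through eta = 0."""
    t = np.asarray(t, dtype=float)
    out = v0 * t * _phi(eta * t)
    return float(out) if out.ndim == 0 else out


def linear_initial_velocity(
    c: ProgressCurve, k: int = 2, through_origin: bool = True
) -> float:
    """OLS slope over the first ``k`` nonzero time points.

    Origin-constrained by default (the t=0 product is zero by
    normalisation); set ``through_origin=False`` for a free intercept.
    """
    t = c.times_h[1 : k + 1]
    p = c.product_uM[1 : k + 1]
    if through_origin:
        t = np.concatenate([[0.0], t])
        p = np.concatenate([[c.product_uM[0]], p])
        return float(np.sum(t * p) / np.sum(t * t))
    if t.size < 2:
        raise ValueError("free-intercept slope needs >= 2 nonzero times")
    return float(np.polyfit(t, p, 1)[0])


def fit_progress(c: ProgressCurve, linear_k: int = 2) -> ProgressFit:
    """Least-squares (v0, eta) for one progress curve.

    Multi-starts over eta in {-0.05, 0, 0.02, 0.05, 0.1} 1/h with eta
    bounded to [-1, 1]; keeps the best residual sum of squares.  An
    all-zero curve returns v0 = 0 with eta flagged undefined.
    """
    t, p = c.times_h, c.product_uM
    if np.count_nonzero(t) < 3:
        raise ValueError("need at least 3 time points beyond t=0")
    lin_v0 = linear_initial_velocity(c, k=linear_k)
    if np.all(p == 0):
        return ProgressFit(0.0, 0.0, 0.0, math.inf, 0.0, lin_v0,
                           c.condition_id, eta_defined=False)

    def resid(theta):
        return eval_progress(theta[0], theta[1], t) - p

    v0_guess = max(lin_v0, 1e-6)
    best = None
    for eta0 in _ETA_STARTS:
        sol = least_squares(
            resid, x0=[v0_guess, eta0],
            bounds=([0.0, _ETA_BOUNDS[0]], [np.inf, _ETA_BOUNDS[1]]),
            method="trf",
        )
        if sol.success and (best is None or sol.cost < best.cost):
            best = sol
    if best is None:
        raise RuntimeError("progress fit failed from every start")

    rss = float(np.sum(best.fun**2))
    dof = max(t.size - 2, 1)
    s2 = rss / dof
    jtj = best.jac.T @ best.jac
    try:
        cov = s2 * np.linalg.inv(jtj)
        v0_se = math.sqrt(max(cov[0, 0], 0.0))
        eta_se = math.sqrt(max(cov[1, 1], 0.0))
    except np.linalg.LinAlgError:
        v0_se = eta_se = math.inf
    return ProgressFit(
        v0=float(best.x[0]), eta=float(best.x[1]),
        v0_se=v0_se, eta_se=eta_se, rss=rss,
        linear_v0=lin_v0, condition_id=c.condition_id,
    )


def classify_nonlinearity(f: ProgressFit, z: float = 2.0) -> str:
    """'activation' (eta < -z*se), 'deceleration' (eta > z*se) or 'linear'."""
    if not f.eta_defined or not math.isfinite(f.eta_se):
        return "linear"
    if f.eta < -z * f.eta_se:
        return "activation"
    if f.eta > z * f.eta_se:
        return "deceleration"
    return "linear"
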