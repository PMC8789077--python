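"""Gel-shift (EMSA) binding analysis.

Association constants for 1:1 conjugate-tRNA binding are obtained two
ways, matching the two ways such gel-shift data are analysed in
practice:

* :func:`ka_from_fraction_bound` - closed form from a single measured
  bound fraction ``alpha`` at known total concentrations,

  .. math::

     K_a = \\frac{\\alpha}{[BC]_0 (1-\\alpha)
           \\left(1 - \\alpha \\frac{[tRNA]_0}{[BC]_0}\\right)}

  which is exact for 1:1 stoichiometry below saturation;

* :func:`fit_binding_curve` - least-squares fit of the exact
  mass-action isotherm (the quadratic solution for the bound fraction)
  across a titration of conjugate concentrations at fixed tRNA.

Concentrations are in uM; association constants are reported in M^-1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import brentq, least_squares

__all__ = [
    "BindingMeasurement",
    "BindingFit",
    "BindingError",
    "ka_from_fraction_bound",
    "bound_fraction",
    "fit_binding_curve",
]


class BindingError(ValueError):
    """Raised for measurements outside the model's domain or unfittable data."""


@dataclass(frozen=True)
class BindingMeasurement:
    """A single gel-shift point: total concentrations and bound fraction."""

    conjugate_uM: float
    trna_uM: float
    fraction_bound: float
    sd: float | None = None

    def __post_init__(self) -> None:
        if self.conjugate_uM <= 0 or self.trna_uM <= 0:
            raise BindingError("total concentrations must be positive")
        if not 0.0 <= self.fraction_bound:
            raise BindingError("fraction bound must be non-negative")


@dataclass(frozen=True)
class BindingFit:
    """Curve-fit result: Ka (M^-1), its standard error, and the conjugate
    concentration (uM) at which the isotherm predicts 99% binding."""

    ka: float
    ka_se: float
    plateau_uM: float
    rss: float
    n: int


def ka_from_fraction_bound(m: BindingMeasurement) -> float:
    """Closed-form Ka (M^-1) from one bound-fraction measurement.

    Undefined at saturation: requires ``alpha < 1`` and
    ``alpha * [tRNA]0/[BC]0 < 1`` (otherwise no free conjugate remains
    and the closed form diverges).
    """
    a = m.fraction_bound
    ratio = m.trna_uM / m.conjugate_uM
    if a >= 1.0 or a * ratio >= 1.0:
        raise BindingError(
            "bound fraction at or beyond saturation; closed form undefined"
        )
    bc0_M = m.conjugate_uM * 1e-6
    return a / (bc0_M * (1.0 - a) * (1.0 - a * ratio))


def bound_fraction(ka_M: float, conjugate_uM: float, trna_uM: float) -> float:
    """Exact 1:1 mass-action bound fraction of tRNA.

    Solves ``C + T <-> CT`` with association constant ``ka_M`` (M^-1)
    at total concentrations in uM, via the stable quadratic root.
    """
    if ka_M <= 0:
        return 0.0
    kd_uM = 1e6 / ka_M
    c0, t0 = conjugate_uM, trna_uM
    b = c0 + t0 + kd_uM
    # stable form of the smaller root of x^2 - b x + c0 t0 = 0
    disc = math.sqrt(b * b - 4.0 * c0 * t0)
    bound = 2.0 * c0 * t0 / (b + disc)
    return bound / t0


def fit_binding_curve(
    titration: Sequence[BindingMeasurement],
    ka_init_M: float = 1e6,
) -> BindingFit:
    """Weighted least-squares fit of the exact-binding isotherm.

    The titration must hold the tRNA total fixed and span at least four
    distinct conjugate concentrations.  Ka is fitted on a log scale;
    the standard error comes from the Gauss-Newton curvature.  Weights
    are uniform unless per-point standard deviations are supplied.
    """
    if len(titration) < 4:
        raise BindingError("need at least 4 titration points")
    conc = np.array([m.conjugate_uM for m in titration], dtype=float)
    if len(np.unique(conc)) < 4:
        raise BindingError("need >= 4 distinct conjugate concentrations")
    trna = np.array([m.trna_uM for m in titration], dtype=float)
    if not np.allclose(trna, trna[0]):
        raise BindingError("titration must be at fixed total tRNA")
    alpha = np.array([m.fraction_bound for m in titration], dtype=float)
    if np.all(alpha == 0.0):
        raise BindingError("no binding signal: all bound fractions are zero")
    sds = np.array(
        [1.0 if m.sd is None else m.sd for m in titration], dtype=float
    )

    def resid(logka: np.ndarray) -> np.ndarray:
        ka = 10.0 ** logka[0]
        pred = np.array([bound_fraction(ka, c, t) for c, t in zip(conc, trna)])
        return (pred - alpha) / sds

    sol = least_squares(resid, x0=[math.log10(ka_init_M)], method="lm")
    if not sol.success:
        raise BindingError(f"binding fit failed: {sol.message}; residuals {sol.fun}")
    ka = 10.0 ** sol.x[0]
    # curvature-based SE, propagated from the log10 scale
    dof = max(len(conc) - 1, 1)
    s2 = float(np.sum(sol.fun**2)) / dof
    jtj = float((sol.jac.T @ sol.jac)[0, 0])
    if jtj > 0:
        se_log = math.sqrt(s2 / jtj)
        ka_se = ka * math.log(10.0) * se_log
    else:  # pragma: no cover - degenerate design
        ka_se = math.inf

    t0 = float(trna[0])
    plateau = _plateau_conc(ka, t0)
    return BindingFit(
        ka=ka, ka_se=ka_se, plateau_uM=plateau,
        rss=float(np.sum(sol.fun**2)), n=len(conc),
    )


def _plateau_conc(ka_M: float, trna_uM: float, level: float = 0.99) -> float:
    """Conjugate concentration at which the isotherm reaches ``level`` bound."""
    f = lambda c: bound_fraction(ka_M, c, trna_uM) - level
    hi = 1.0
    while f(hi) < 0 and hi < 1e9:
        hi *= 10.0
    if f(hi) < 0:  # pragma: no cover - absurdly weak binding
        return math.inf
    return brentq(f, 1e-12, hi)
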