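"""Independent brute-force oracles used by the test suite.

Everything here is deliberately written without reference to the
package's own solvers: nested scalar bisection for the binding and
speciation equilibria, and a black-box ODE integration for the
Michaelis-Menten limit.  Slow but simple.
"""

from __future__ import annotations

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq


def bisect_binding_alpha(ka_M: float, conjugate_uM: float,
                         trna_uM: float) -> float:
    """1:1 binding bound-fraction by bisection on free conjugate."""
    ka = ka_M * 1e-6  # per uM

    def f(c_free: float) -> float:
        bound = ka * c_free * trna_uM / (1.0 + ka * c_free)
        return c_free + bound - conjugate_uM

    c_free = brentq(f, 0.0, conjugate_uM, xtol=1e-15, rtol=8.9e-16)
    bound = ka * c_free * trna_uM / (1.0 + ka * c_free)
    return bound / trna_uM


def _self_complexed(x: float, K: float, mode: str) -> float:
    if mode == "hairpin":
        return x / K
    return 2.0 * x * x / K


def bisect_speciation(s_tot, c_tot, p_tot, *, Kcs, Kss, Kds, Kp, Ks, Kc,
                      s_mode="hairpin", c_mode="duplex"):
    """Free (s, c, p) by nested bisection on the conservation laws."""

    def s_of_c(c):
        if s_tot == 0:
            return 0.0

        def f(s):
            return (s + _self_complexed(s, Ks, s_mode)
                    + c * s / Kcs + c * s / Kss
                    + 2 * c * s * s / (Kss * Kds) - s_tot)

        return brentq(f, 0.0, s_tot, xtol=1e-16, rtol=8.9e-16, maxiter=500)

    def p_of_c(c):
        return p_tot / (1.0 + c / Kp)

    if c_tot == 0:
        return s_of_c(0.0), 0.0, p_tot

    def g(c):
        s = s_of_c(c)
        return (c + _self_complexed(c, Kc, c_mode)
                + c * s / Kcs + c * s / Kss + c * s * s / (Kss * Kds)
                + c * p_of_c(c) / Kp - c_tot)

    c = brentq(g, 0.0, c_tot, xtol=1e-16, rtol=8.9e-16, maxiter=500)
    return s_of_c(c), c, p_of_c(c)


def mm_ode_product(k_cat, Km, s0, c0, t_grid, rtol=1e-10):
    """Classical single-substrate Michaelis-Menten progress curve.

    Treats the catalyst as unsequestered (valid for c0 << s0) and uses
    total remaining substrate, dP/dt = k_cat c0 (s0-P) / (Km + s0 - P).
    """

    def rhs(_, y):
        s = s0 - y[0]
        return [k_cat * c0 * s / (Km + s)]

    sol = solve_ivp(rhs, (t_grid[0], t_grid[-1]), [0.0], t_eval=t_grid,
                    rtol=rtol, atol=1e-12)
    return sol.y[0]
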