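"""Instantaneous-dissolution (Higuchi) reference model for a spherical matrix.

Under the classical assumptions — dissolution much faster than diffusion
and a pseudo-steady-state dissolved-drug profile across the depletion
shell — the depletion-front position eta_star(tau) satisfies the implicit
relation

    1 + 2 a^3 - 3 a^2 + K [4 a^2 + ln(1/a) - 1 - a - 2 a^3] = 6 K tau,

with a = eta_star, and the released fraction follows from the material
left in the un-depleted core (total concentration 1) plus the dissolved
drug held in the depletion shell:

    F = 1 - a^3 - integral_a^1 phi_pss(eta) 3 eta^2 d eta.

The pseudo-steady-state shell profile is the quasi-static solution of the
spherical Laplace equation with phi = K at the front and the sink phi = 0
at the surface,

    phi_pss(eta) = K (1/eta - 1) / (1/a - 1),

which gives the shell integral the closed form (K/2) a (1-a) (1+2a).

The implicit relation is implemented verbatim in its classical form
(including the K-bracketed group, with no algebraic rearrangement); its
left side has a double root at a = 1 and grows like K ln(1/a) as a -> 0,
so the root is unique on (0, 1] and is found by bracketed Brent iteration
with a Newton polish.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "HiguchiSolution",
    "higuchi_front",
    "pss_profile",
    "higuchi_fraction",
    "higuchi_curve",
    "shell_integral_closed_form",
]


@dataclass(frozen=True)
class HiguchiSolution:
    """Front position and released fraction on a time grid."""

    tau: np.ndarray
    eta_star: np.ndarray
    fraction_released: np.ndarray


def _front_equation_lhs(a: float, K: float) -> float:
    return (
        1.0
        + 2.0 * a**3
        - 3.0 * a**2
        + K * (4.0 * a**2 + np.log(1.0 / a) - 1.0 - a - 2.0 * a**3)
    )


def _front_equation_dlhs_dx(a: float, K: float) -> float:
    """d/dx of the front equation's left side under a = exp(-x) (tends to K
    as a -> 0, so Newton in x stays well conditioned for tiny fronts)."""
    return -a * (6.0 * a * a - 6.0 * a + K * (8.0 * a - 1.0 / a - 1.0 - 6.0 * a * a))


#: Largest log-front-recession resolved; beyond it (eta* < e^-700) the
#: released fraction is 1 to double precision and the front is reported as 0.
_X_CEIL = 700.0


def higuchi_front(tau: float, K: float) -> float:
    """Depletion-front position eta_star of the Higuchi model at time tau.

    Returns exactly 1 at tau = 0 and 0 once the front has receded beyond
    floating-point resolution (release numerically complete).  The root
    is bracketed in x = ln(1/eta_star), where the left side grows linearly
    (~K x) instead of diverging, then polished by Newton steps so the
    equation residual is at rounding level (< 1e-10) even for tiny fronts.
    """
    if tau < 0.0:
        raise ValueError(f"tau must be nonnegative, got {tau!r}")
    if not 0.0 < K < 1.0:
        raise ValueError(f"K must lie in (0, 1), got {K!r}")
    if tau == 0.0:
        return 1.0
    target = 6.0 * K * tau

    def g(x: float) -> float:
        return _front_equation_lhs(np.exp(-x), K) - target

    if g(_X_CEIL) <= 0.0:
        # front beyond resolution: matrix numerically exhausted
        return 0.0
    # the left side has a double root at eta* = 1: near x = 0 it behaves as
    # (3 - 3K/2) x^2, and below ~1e-15 it is pure rounding noise, so tiny
    # targets are solved by the expansion instead of bracketing
    curv = 3.0 - 1.5 * K
    x0 = np.sqrt(target / curv)
    if target < 1e-9:
        return float(np.exp(-x0))
    x = brentq(g, 0.5 * x0, _X_CEIL, xtol=1e-13, rtol=8.9e-16, maxiter=200)
    # Newton polish in x (derivative ~ K at small a, well conditioned)
    for _ in range(3):
        a = np.exp(-x)
        slope = _front_equation_dlhs_dx(a, K)
        if slope == 0.0:
            break
        step = g(x) / slope
        if not np.isfinite(step) or abs(step) > 1.0:
            break
        x -= step
        if abs(step) < 1e-15 * max(1.0, abs(x)):
            break
    return float(np.exp(-x))


def pss_profile(eta, eta_star: float, K: float):
    """Pseudo-steady-state dissolved profile in the depletion shell.

    phi(eta) = K (1/eta - 1)/(1/eta_star - 1) for eta_star < eta <= 1;
    saturated (K) at the front, zero at the surface sink.
    """
    if not 0.0 < eta_star < 1.0:
        raise ValueError(f"eta_star must lie in (0, 1), got {eta_star!r}")
    eta_arr = np.asarray(eta, dtype=float)
    if np.any(eta_arr <= eta_star) or np.any(eta_arr > 1.0):
        raise ValueError("eta must lie in (eta_star, 1]")
    out = K * (1.0 / eta_arr - 1.0) / (1.0 / eta_star - 1.0)
    if np.isscalar(eta) or eta_arr.ndim == 0:
        return float(out)
    return out


def shell_integral_closed_form(eta_star: float, K: float) -> float:
    """Closed form of integral_{eta_star}^1 phi_pss 3 eta^2 d eta.

    Equals (K/2) * eta_star * (1 - eta_star) * (1 + 2 eta_star).
    """
    a = eta_star
    return 0.5 * K * a * (1.0 - a) * (1.0 + 2.0 * a)


def higuchi_fraction(tau: float, K: float) -> float:
    """Released fraction of the Higuchi model at time tau.

    F = 1 - eta_star^3 - (shell integral); the un-depleted core retains
    the full dimensionless concentration 1.
    """
    a = higuchi_front(tau, K)
    if a >= 1.0:
        return 0.0
    if a <= 0.0:
        return 1.0
    return 1.0 - a**3 - shell_integral_closed_form(a, K)


def higuchi_curve(tau_grid, K: float) -> HiguchiSolution:
    """Evaluate front position and released fraction on a time grid."""
    tau_grid = np.asarray(tau_grid, dtype=float)
    eta_star = np.array([higuchi_front(t, K) for t in tau_grid])
    frac = np.array([higuchi_fraction(t, K) for t in tau_grid])
    return HiguchiSolution(tau=tau_grid, eta_star=eta_star, fraction_released=frac)
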