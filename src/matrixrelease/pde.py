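"""Method-of-lines solution of the coupled dissolution-diffusion system.

The dimensionless governing equations on the unit sphere are

    d phi   / d tau = (1/eta) d2(eta phi)/d eta2 + S(phi, phi_a)
    d phi_a / d tau = -S(phi, phi_a)

with the dissolution source

    S = G * (phi_a / (1-K))**n * (K - phi)

active only where un-dissolved drug remains.  Initial conditions are a
saturated dissolved phase, phi = K and phi_a = 1 - K everywhere; boundary
conditions are symmetry at the center and a perfect sink phi = 0 at the
surface.

Discretization: a uniform radial mesh (2000 nodes by default); the
spherical Laplacian is applied to w = eta*phi with a standard central
difference, and at the center the removable singularity is replaced by its
symmetry limit 6*(phi_1 - phi_0)/h**2.  The surface node is pinned to
phi = 0 (its un-dissolved phase still dissolves, which reproduces the
exact surface solution).  Time integration uses LSODA with the banded
Jacobian structure of the interleaved state vector (phi and phi_a
alternating, bandwidth 2); an implicit stiff method is required for large
G.

The moving depletion boundary is not tracked explicitly: the unit-step
factor of the source is realized pointwise through the local solid
content.  The source is switched off below ``front_epsilon`` and, to keep
the right-hand side Lipschitz for the integrator, tapered linearly over a
narrow solid-content ramp (width 1e-6, holding ~1e-6 of the load) instead
of jumping — a hard per-node switch makes the planar (n = 0) depletion
collapse pathologically slow to integrate.  For n > 0 the source already
vanishes continuously as phi_a -> 0.  phi_a is clamped at 0 inside the
power law because n < 1 makes the source derivative singular there and
tiny negative overshoots would otherwise produce NaNs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import simpson, solve_ivp

from .analytic import critical_time
from .core import DimensionlessParams

__all__ = [
    "Mesh",
    "SolverOptions",
    "StateProfile",
    "ReleaseCurve",
    "dissolution_source",
    "default_output_grid",
    "solve",
    "release_fraction",
    "depletion_front",
    "release_rate",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Mesh:
    """Uniform radial mesh on [0, 1] with ``n_points`` nodes inclusive."""

    n_points: int = 2000

    def __post_init__(self) -> None:
        if self.n_points < 3:
            raise ValueError(f"mesh needs at least 3 nodes, got {self.n_points!r}")

    @property
    def eta(self) -> np.ndarray:
        return np.linspace(0.0, 1.0, self.n_points)

    @property
    def h(self) -> float:
        return 1.0 / (self.n_points - 1)


@dataclass(frozen=True)
class SolverOptions:
    """Numerical controls for the method-of-lines integration.

    ``rel_tol`` is the time integrator's relative tolerance, ``abs_tol``
    its absolute tolerance; ``quad_rel_tol`` the release-fraction
    quadrature tolerance; ``front_epsilon`` the un-dissolved threshold
    below which the dissolution source is switched off (the pointwise
    realization of the depletion front); ``output_tau`` an optional
    strictly increasing output grid (defaults to a log-spaced grid around
    the critical time, see :func:`default_output_grid`).
    """

    rel_tol: float = 1e-3
    abs_tol: float = 1e-8
    quad_rel_tol: float = 1e-6
    front_epsilon: float = 1e-9
    output_tau: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        for name in ("rel_tol", "abs_tol", "quad_rel_tol", "front_epsilon"):
            if not getattr(self, name) > 0.0:
                raise ValueError(f"{name} must be > 0")
        if self.output_tau is not None:
            out = np.asarray(self.output_tau, dtype=float)
            if out.ndim != 1 or out.size == 0:
                raise ValueError("output_tau must be a nonempty 1-D array")
            if np.any(np.diff(out) <= 0.0):
                raise ValueError("output_tau must be strictly increasing")
            if out[0] < 0.0:
                raise ValueError("output_tau must start at tau >= 0")
            object.__setattr__(self, "output_tau", out)


@dataclass(frozen=True)
class StateProfile:
    """Radial concentration fields at one dimensionless time."""

    tau: float
    eta: np.ndarray
    phi: np.ndarray
    phi_a: np.ndarray


@dataclass(frozen=True)
class ReleaseCurve:
    """Release history: fraction released, release rate, front position.

    ``rate`` is the instantaneous release rate dF/dtau evaluated from the
    surface flux, -3 * dphi/deta at eta = 1, which is the exact time
    derivative of the released fraction (no differencing noise);
    :func:`release_rate` provides the finite-difference alternative
    computed from F(tau) alone.
    """

    tau: np.ndarray
    fraction_released: np.ndarray
    rate: np.ndarray
    eta_star: np.ndarray
    params: DimensionlessParams


#: Width (in solid fraction) of the linear taper that realizes the
#: depletion unit step continuously; holds ~1e-6 of the load.
FRONT_RAMP = 1e-6


def dissolution_source(phi, phi_a, params: DimensionlessParams,
                       front_epsilon: float = 1e-9):
    """Noyes-Whitney dissolution source S = G (phi_a/(1-K))**n (K - phi).

    Zero wherever phi_a <= front_epsilon (exhausted solid cannot
    dissolve), tapering linearly over the last ``FRONT_RAMP`` of solid
    content so the depletion switch stays Lipschitz; phi_a is clamped at
    0 inside the power law.
    """
    phi = np.asarray(phi, dtype=float)
    phi_a = np.asarray(phi_a, dtype=float)
    K, G, n = params.K, params.G, params.n
    clamped = np.maximum(phi_a, 0.0)
    if n == 0.0:
        area = np.ones_like(clamped)
    else:
        area = (clamped / (1.0 - K)) ** n
    S = G * area * (K - phi) * np.clip(clamped / FRONT_RAMP, 0.0, 1.0)
    S = np.where(phi_a > front_epsilon, S, 0.0)
    if S.ndim == 0:
        return float(S)
    return S


def default_output_grid(params: DimensionlessParams, n_points: int = 400,
                        tau_end: float | None = None) -> np.ndarray:
    """Log-spaced output grid spanning [1e-4 tau_c, 50 tau_c] by default.

    The logarithmic spacing resolves both the initial burst and the slow
    diffusive tail, matching the log-time presentation of release curves.
    """
    tau_c = critical_time(params)
    hi = 50.0 * tau_c if tau_end is None else float(tau_end)
    lo = min(1e-4 * tau_c, 1e-4 * hi)
    return np.geomspace(lo, hi, n_points)


def _rhs_factory(params: DimensionlessParams, mesh: Mesh, front_epsilon: float):
    K, G, n = params.K, params.G, params.n
    eta = mesh.eta
    h = mesh.h
    inv_h2 = 1.0 / (h * h)
    inv_eta_interior = 1.0 / eta[1:-1]
    one_minus_K = 1.0 - K

    def rhs(tau: float, y: np.ndarray) -> np.ndarray:
        phi = y[0::2]
        phi_a = y[1::2]
        clamped = np.maximum(phi_a, 0.0)
        if n == 0.0:
            S = G * (K - phi)
        else:
            S = G * (clamped / one_minus_K) ** n * (K - phi)
        S *= np.clip(clamped / FRONT_RAMP, 0.0, 1.0)
        np.copyto(S, 0.0, where=phi_a <= front_epsilon)
        w = eta * phi
        dphi = np.empty_like(phi)
        dphi[1:-1] = (w[2:] - 2.0 * w[1:-1] + w[:-2]) * inv_h2 * inv_eta_interior
        dphi[1:-1] += S[1:-1]
        dphi[0] = 6.0 * (phi[1] - phi[0]) * inv_h2 + S[0]
        dphi[-1] = 0.0  # surface pinned to the sink condition
        dy = np.empty_like(y)
        dy[0::2] = dphi
        dy[1::2] = -S
        return dy

    return rhs


def solve(
    params: DimensionlessParams,
    mesh: Mesh | None = None,
    opts: SolverOptions | None = None,
) -> tuple[ReleaseCurve, list[StateProfile]]:
    """Integrate the coupled system and return the release curve and states.

    Returns one :class:`StateProfile` per requested output time plus the
    derived :class:`ReleaseCurve`.  Output times of exactly 0 return the
    initial condition.
    """
    mesh = mesh or Mesh()
    opts = opts or SolverOptions()
    out_tau = (
        opts.output_tau
        if opts.output_tau is not None
        else default_output_grid(params)
    )

    eta = mesh.eta
    N = mesh.n_points
    y0 = np.empty(2 * N)
    y0[0::2] = params.K
    y0[1::2] = 1.0 - params.K
    y0[2 * N - 2] = 0.0  # surface sink from tau = 0+

    rhs = _rhs_factory(params, mesh, opts.front_epsilon)
    t_end = out_tau[-1]
    sol = solve_ivp(
        rhs,
        (0.0, t_end),
        y0,
        method="LSODA",
        t_eval=out_tau,
        rtol=opts.rel_tol,
        atol=opts.abs_tol,
        lband=2,
        uband=2,
    )
    if not sol.success:
        raise RuntimeError(
            f"stiff integration failed for K={params.K}, G={params.G}, "
            f"n={params.n}: {sol.message} (last tau reached: "
            f"{sol.t[-1] if sol.t.size else 0.0})"
        )
    if not np.all(np.isfinite(sol.y)):
        raise RuntimeError(
            f"non-finite state encountered for K={params.K}, G={params.G}, "
            f"n={params.n}"
        )
    logger.info(
        "solved K=%g G=%g n=%g: %d rhs evaluations, %d jacobian evaluations, "
        "final tau=%g", params.K, params.G, params.n, sol.nfev, sol.njev, t_end,
    )

    states: list[StateProfile] = []
    frac = np.empty(out_tau.size)
    rate = np.empty(out_tau.size)
    eta_star = np.empty(out_tau.size)
    h = mesh.h
    for j, tau_j in enumerate(out_tau):
        phi = sol.y[0::2, j].copy()
        phi_a = sol.y[1::2, j].copy()
        state = StateProfile(tau=float(tau_j), eta=eta, phi=phi, phi_a=phi_a)
        states.append(state)
        frac[j] = release_fraction(state)
        # surface flux, one-sided second order with phi(1) = 0
        dphi_surface = (3.0 * phi[-1] - 4.0 * phi[-2] + phi[-3]) / (2.0 * h)
        rate[j] = -3.0 * dphi_surface
        eta_star[j] = depletion_front(state, opts.front_epsilon)

    curve = ReleaseCurve(
        tau=np.asarray(out_tau, dtype=float),
        fraction_released=frac,
        rate=rate,
        eta_star=eta_star,
        params=params,
    )
    return curve, states


def release_fraction(state: StateProfile) -> float:
    """Released fraction F = integral_0^1 (1 - phi - phi_a) 3 eta^2 d eta.

    Evaluated by composite Simpson quadrature on the mesh nodes; on the
    default 2000-node mesh the quadrature error is far below the 1e-6
    target.
    """
    integrand = (1.0 - state.phi - state.phi_a) * 3.0 * state.eta**2
    return float(simpson(integrand, x=state.eta))


def depletion_front(state: StateProfile, front_epsilon: float = 1e-9) -> float:
    """Position of the depletion front: outermost eta with un-dissolved drug.

    Returns the largest mesh eta where phi_a exceeds ``front_epsilon``
    (1 while the surface is un-depleted, 0 once the solid phase is fully
    exhausted).
    """
    mask = state.phi_a > front_epsilon
    if not np.any(mask):
        return 0.0
    return float(state.eta[np.nonzero(mask)[0][-1]])


def release_rate(curve: ReleaseCurve) -> np.ndarray:
    """dF/dtau by centered finite differences on the (nonuniform) tau grid.

    Exact for linear F; one-sided at the endpoints.  This is the
    curve-level alternative to the surface-flux rate stored on the curve
    and is used to cross-check it.
    """
    tau = curve.tau
    if tau.size < 3:
        raise ValueError("need at least 3 output times to differentiate")
    if np.any(np.diff(tau) == 0.0):
        raise ValueError("duplicate tau values in release curve")
    return np.gradient(curve.fraction_released, tau, edge_order=2)
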