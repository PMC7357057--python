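"""Parameter containers and physical-to-dimensionless conversion.

The release system is a non-swellable spherical matrix of radius ``r0``
uniformly loaded with dissolved drug (concentration ``C``, bounded by the
solubility ``Cs``) and un-dissolved dispersed drug particles (concentration
``Ca``).  Release proceeds by dissolution of the dispersed particles
(Noyes-Whitney kinetics, with a particle-shape-dependent surface-area law
``A = A0 (Ca/Ca0)^n``) followed by Fickian diffusion to a perfect-sink
medium.

Two dimensionless groups govern the dynamics:

``K = Cs / (Cs + Ca0)``
    solubility-to-total-loading ratio; small K means a mostly solid,
    high-loading system.
``G = k * A0 * r0**2 / D``
    dissolution-to-diffusion rate ratio; G >> 1 approaches instantaneous
    dissolution (the Higuchi limit).

Time and radius are scaled as ``tau = D t / r0**2`` and ``eta = r / r0``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

__all__ = [
    "PLANAR",
    "CYLINDRICAL",
    "SPHERICAL",
    "PhysicalParams",
    "DimensionlessParams",
    "nondimensionalize",
    "tau_of_time",
    "time_of_tau",
]

#: Shape factor of platelet-like (planar) dispersed particles.
PLANAR = 0.0
#: Shape factor of cylindrical (rod-like) dispersed particles.
CYLINDRICAL = 0.5
#: Shape factor of spherical dispersed particles.
SPHERICAL = 2.0 / 3.0


def _require_positive(name: str, value: float) -> float:
    value = float(value)
    if not value > 0.0:
        raise ValueError(f"{name} must be strictly positive, got {value!r}")
    return value


def _validate_shape_factor(n: float) -> float:
    n = float(n)
    if not 0.0 <= n < 1.0:
        raise ValueError(f"shape factor n must lie in [0, 1), got {n!r}")
    return n


@dataclass(frozen=True)
class PhysicalParams:
    """Dimensional parameters of one release system.

    Units must be mutually consistent; no unit inference is performed.

    Parameters
    ----------
    D : float
        Drug diffusion coefficient in the matrix (length**2 / time).
    k : float
        Dissolution rate constant of the Noyes-Whitney law (the product
        ``k * A0`` acts as a first-order rate constant, 1/time).
    A0 : float
        Initial dispersed-drug surface area per unit matrix volume.
    r0 : float
        Radius of the spherical matrix (length).
    Cs : float
        Drug solubility in the matrix phase (mass / volume).
    Ca0 : float
        Initial un-dissolved (dispersed) drug concentration (mass / volume).
    n : float
        Particle shape factor in ``A = A0 (Ca/Ca0)**n``; 0 for planar,
        1/2 for cylindrical, 2/3 for spherical particles.
    """

    D: float
    k: float
    A0: float
    r0: float
    Cs: float
    Ca0: float
    n: float = PLANAR

    def __post_init__(self) -> None:
        for name in ("D", "k", "A0", "r0", "Cs", "Ca0"):
            object.__setattr__(self, name, _require_positive(name, getattr(self, name)))
        object.__setattr__(self, "n", _validate_shape_factor(self.n))

    @property
    def Ct(self) -> float:
        """Total initial drug loading Cs + Ca0."""
        return self.Cs + self.Ca0


@dataclass(frozen=True)
class DimensionlessParams:
    """The triple (K, G, n) that fully defines one dimensionless system.

    K is restricted to the open interval (0, 1): K = 0 would mean an
    insoluble drug (no release at all) and K = 1 a system with no dispersed
    phase (pure diffusion); both are degenerate for the dissolution source
    term and the critical-time expression and are rejected.
    """

    K: float
    G: float
    n: float = PLANAR

    def __post_init__(self) -> None:
        K = float(self.K)
        if not 0.0 < K < 1.0:
            raise ValueError(
                f"K must lie strictly inside (0, 1); got {K!r}. "
                "K=0 (insoluble drug) and K=1 (no dispersed phase) are degenerate."
            )
        object.__setattr__(self, "K", K)
        G = float(self.G)
        if not G > 0.0:
            raise ValueError(f"G must be strictly positive, got {G!r}")
        object.__setattr__(self, "G", G)
        object.__setattr__(self, "n", _validate_shape_factor(self.n))

    def with_shape(self, n: float) -> "DimensionlessParams":
        """Same (K, G) with a different particle shape factor."""
        return replace(self, n=n)


def nondimensionalize(p: PhysicalParams) -> DimensionlessParams:
    """Convert physical parameters to the dimensionless triple (K, G, n).

    ``K = Cs/(Cs + Ca0)`` and ``G = k A0 r0**2 / D``; the shape factor is
    passed through unchanged.
    """
    K = p.Cs / p.Ct
    G = p.k * p.A0 * p.r0**2 / p.D
    return DimensionlessParams(K=K, G=G, n=p.n)


def tau_of_time(t: float, p: PhysicalParams) -> float:
    """Dimensionless time ``tau = D t / r0**2`` of a physical time ``t >= 0``."""
    if t < 0.0:
        raise ValueError(f"time must be nonnegative, got {t!r}")
    return p.D * t / p.r0**2


def time_of_tau(tau: float, p: PhysicalParams) -> float:
    """Physical time of a dimensionless time; inverse of :func:`tau_of_time`."""
    if tau < 0.0:
        raise ValueError(f"tau must be nonnegative, got {tau!r}")
    return tau * p.r0**2 / p.D
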