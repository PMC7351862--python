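"""Plasmon-polariton dispersion of a periodic chain of electrolyte segments.

A chain of identical spherical segments (radius ``a``, period ``d``,
embedded in a host of relative permittivity ``eps``) couples neighbouring
dipole surface plasmons through the retarded dipole field.  In the wave
ansatz D ~ exp(-i k l d - i omega t) the chain dynamics reduce, per
polarization alpha in {longitudinal, transverse}, to the scalar relation

    omega^2 + i (2/tau0) omega - omega1^2 (1 - g F_alpha(x, u)) = 0,

with the dimensionless variables

    x = k d   in (0, 2 pi),      u = omega d / v,    v = c / sqrt(eps),
    g = (a/d)^3                  (dipole coupling strength),

and the retarded lattice sums ("structure factors")

    F_z      = 4 sum_m [cos(mx) cos(mu)/m^3 + u cos(mx) sin(mu)/m^2]
               + 2i [u^3/3 + 2 sum_m (cos(mx) sin(mu)/m^3
                                      - u cos(mx) cos(mu)/m^2)]
    F_x(y)   = -2 sum_m [cos(mx) cos(mu)/m^3 + u cos(mx) sin(mu)/m^2
                         - u^2 cos(mx) cos(mu)/m]
               + i [2 u^3/3 - 2 sum_m (cos(mx) sin(mu)/m^3
                                       - u cos(mx) cos(mu)/m^2
                                       - u^2 cos(mx) sin(mu)/m)].

The u^3 terms are the Lorentz (radiative) self-friction of a single dipole.
In the subluminal region u < x < 2 pi - u the lattice sums cancel them
exactly -- Im F_alpha == 0 -- so the only damping left is Ohmic.  The sums
are evaluated in closed form (Bernoulli-polynomial Fourier series and
Clausen functions), making the cancellation explicit to machine precision.

Sign conventions: time factor exp(-i omega t), so damped modes have
Im omega <= 0; the principal square root with Re >= 0 is taken throughout.
The structure factor is evaluated on the real frequency axis (u from
Re omega), i.e. damping is treated perturbatively inside the lattice sum,
which keeps the retarded series convergent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import _clausen as _cl
from .constants import LIGHT_SPEED
from .plasma import InvalidParameterError

LONGITUDINAL = "longitudinal"
TRANSVERSE = "transverse"

#: half-width of the light-cone exclusion band, in units of x = k d
LIGHT_CONE_HALF_WIDTH = 1e-4


class LightConeError(ValueError):
    """Evaluation requested on or too near a light-cone singularity."""


@dataclass(frozen=True)
class ChainGeometry:
    """Geometry of the segment chain.

    Parameters
    ----------
    segment_radius : float
        Sphere radius a [m].
    period : float
        Centre-to-centre separation d [m]; must satisfy d >= 2a.
    eps : float
        Relative permittivity of the host medium.
    count : int or None
        Number of segments 2N+1 for a finite chain, or None for the
        infinite (quasi-continuous k) chain.
    """

    segment_radius: float
    period: float
    eps: float = 80.0
    count: int | None = None

    def __post_init__(self):
        if self.segment_radius <= 0 or self.period <= 0:
            raise InvalidParameterError("radius and period must be > 0")
        if self.period < 2.0 * self.segment_radius:
            raise InvalidParameterError(
                f"segments overlap: d = {self.period} < 2a = {2 * self.segment_radius}")
        if self.eps < 1:
            raise InvalidParameterError("eps must be >= 1")
        if self.count is not None and (self.count < 1 or self.count % 2 == 0):
            raise InvalidParameterError("count must be an odd positive integer")

    @property
    def coupling(self) -> float:
        """Dipole coupling strength g = (a/d)^3, in (0, 1/8]."""
        return (self.segment_radius / self.period) ** 3

    @property
    def light_speed_in_medium(self) -> float:
        """Phase velocity of light in the host, v = c / sqrt(eps) [m/s]."""
        return LIGHT_SPEED / math.sqrt(self.eps)

    def dft_k_grid(self) -> np.ndarray:
        """The discrete k grid 2 pi n / ((2N+1) d) of a finite chain."""
        if self.count is None:
            raise InvalidParameterError("dft_k_grid requires a finite count")
        n = np.arange(1, self.count)  # skip k = 0
        return 2.0 * np.pi * n / (self.count * self.period)


@dataclass(frozen=True)
class StructureFactorValue:
    polarization: str
    x: float
    u: float
    value: complex
    singular: bool = False


@dataclass(frozen=True)
class DrivingField:
    """External driving field E0 [V/m] at wavenumber k and frequency omega."""

    amplitude: float
    k: float
    omega: float
    polarization: str = LONGITUDINAL


@dataclass(frozen=True)
class DispersionPoint:
    k: float
    omega: complex
    v_g: float | None
    converged: bool
    iterations: int


@dataclass
class DispersionBranch:
    """Solved branch omega(k) for one polarization.

    Arrays are aligned with ``k``; ``excluded_k`` lists grid points dropped
    inside the light-cone exclusion bands.  ``physically_suppressed`` marks
    the transverse branch, which cannot synchronize with the node firing
    cycle and is therefore not a carrier of the triggering signal.
    """

    geometry: ChainGeometry
    polarization: str
    omega1: float
    inv_tau0: float
    k: np.ndarray = field(repr=False)
    omega: np.ndarray = field(repr=False)
    converged: np.ndarray = field(repr=False)
    iterations: np.ndarray = field(repr=False)
    excluded_k: np.ndarray = field(repr=False)
    v_g: np.ndarray | None = field(default=None, repr=False)

    @property
    def physically_suppressed(self) -> bool:
        return self.polarization == TRANSVERSE

    @property
    def points(self) -> list[DispersionPoint]:
        vg = self.v_g if self.v_g is not None else [None] * len(self.k)
        return [DispersionPoint(float(k), complex(w), None if v is None else float(v),
                                bool(c), int(i))
                for k, w, v, c, i in zip(self.k, self.omega, vg,
                                         self.converged, self.iterations)]


# --------------------------------------------------------------------------
# lattice sums


def static_cosine_sums(x, order: int):
    """Closed-form sums (sum cos(mx)/m^order, sum sin(mx)/m^order).

    ``x`` must reduce to (0, 2 pi) modulo 2 pi; order in {1, 2, 3}.
    These are the u -> 0 building blocks of the structure factors.
    """
    if order not in (1, 2, 3):
        raise InvalidParameterError("order must be 1, 2 or 3")
    y = np.mod(np.asarray(x, dtype=float), 2.0 * np.pi)
    if np.any(y == 0.0):
        raise InvalidParameterError("x must not be a multiple of 2*pi")
    pair = {
        1: (_cl.cos_sum_m1, _cl.sin_sum_m1),
        2: (_cl.cos_sum_m2, _cl.sin_sum_m2),
        3: (_cl.cos_sum_m3, _cl.sin_sum_m3),
    }[order]
    return pair[0](y), pair[1](y)


def _fz_parts(x, u):
    xp, xm = x + u, x - u
    re = (2.0 * (_cl.cos_sum_m3(xm) + _cl.cos_sum_m3(xp))
          + 2.0 * u * (_cl.sin_sum_m2(xp) - _cl.sin_sum_m2(xm)))
    im = (2.0 * u**3 / 3.0
          + 2.0 * (_cl.sin_sum_m3(xp) - _cl.sin_sum_m3(xm))
          - 2.0 * u * (_cl.cos_sum_m2(xp) + _cl.cos_sum_m2(xm)))
    return re, im


def _fx_parts(x, u):
    xp, xm = x + u, x - u
    re = (-(_cl.cos_sum_m3(xm) + _cl.cos_sum_m3(xp))
          - u * (_cl.sin_sum_m2(xp) - _cl.sin_sum_m2(xm))
          + u**2 * (_cl.cos_sum_m1(xm) + _cl.cos_sum_m1(xp)))
    im = (2.0 * u**3 / 3.0
          - (_cl.sin_sum_m3(xp) - _cl.sin_sum_m3(xm))
          + u * (_cl.cos_sum_m2(xp) + _cl.cos_sum_m2(xm))
          + u**2 * (_cl.sin_sum_m1(xp) - _cl.sin_sum_m1(xm)))
    return re, im


def _near_light_cone(x, u, half_width=LIGHT_CONE_HALF_WIDTH):
    x = np.mod(np.asarray(x, dtype=float), 2.0 * np.pi)
    u = np.abs(np.asarray(u, dtype=float))
    return (np.abs(x - u) < half_width) | (np.abs(2.0 * np.pi - x - u) < half_width)


def structure_factor_arrays(x, u, polarization):
    """Vectorized complex F_alpha(x, u) via the closed forms (no cone check)."""
    parts = _fz_parts if polarization == LONGITUDINAL else _fx_parts
    re, im = parts(np.asarray(x, dtype=float), np.asarray(u, dtype=float))
    return re + 1j * im


def structure_factor(x: float, u: float, polarization: str = LONGITUDINAL
                     ) -> StructureFactorValue:
    """Exact structure factor F_alpha at x = k d, u = omega d / v.

    Raises nothing, but flags points inside the light-cone exclusion band as
    ``singular`` (with value NaN) rather than returning an unreliable number.
    """
    if u < 0:
        raise InvalidParameterError("u must be >= 0")
    if polarization not in (LONGITUDINAL, TRANSVERSE):
        raise InvalidParameterError(f"unknown polarization {polarization!r}")
    if bool(_near_light_cone(x, u)):
        return StructureFactorValue(polarization, float(x), float(u),
                                    complex(np.nan, np.nan), singular=True)
    val = complex(structure_factor_arrays(x, u, polarization))
    return StructureFactorValue(polarization, float(x), float(u), val)


def truncated_structure_factor(x: float, u: float,
                               polarization: str = LONGITUDINAL,
                               n_terms: int = 10) -> StructureFactorValue:
    """Partial lattice sum over m = 1..n_terms (finite-chain estimate).

    The Lorentz-friction u^3 terms are kept in full, so the imaginary part
    converges to zero (subluminal region) only as n_terms grows.  Ten terms
    already reproduce the infinite chain to a few per cent away from the
    band edges, which is why ~10 segments behave like an infinite chain.
    """
    if polarization not in (LONGITUDINAL, TRANSVERSE):
        raise InvalidParameterError(f"unknown polarization {polarization!r}")
    m = np.arange(1, n_terms + 1, dtype=float)
    cx = np.cos(m * x)
    cu, su = np.cos(m * u), np.sin(m * u)
    if polarization == LONGITUDINAL:
        re = 4.0 * np.sum(cx * cu / m**3 + u * cx * su / m**2)
        im = 2.0 * (u**3 / 3.0
                    + 2.0 * np.sum(cx * su / m**3 - u * cx * cu / m**2))
    else:
        re = -2.0 * np.sum(cx * cu / m**3 + u * cx * su / m**2
                           - u**2 * cx * cu / m)
        im = (2.0 * u**3 / 3.0
              - 2.0 * np.sum(cx * su / m**3 - u * cx * cu / m**2
                             - u**2 * cx * su / m))
    return StructureFactorValue(polarization, float(x), float(u),
                                complex(re, im))


# --------------------------------------------------------------------------
# dispersion solver


def default_k_grid(geometry: ChainGeometry, n_points: int = 2001) -> np.ndarray:
    """Uniform grid of n_points on (delta, 2 pi/d - delta), delta = 1e-6 * 2 pi/d."""
    k_max = 2.0 * np.pi / geometry.period
    delta = 1e-6 * k_max
    return np.linspace(delta, k_max - delta, n_points)


def light_cone_offsets(geometry: ChainGeometry, omega1: float) -> dict:
    """Positions (in x = k d) of the light-cone crossings at omega = omega1.

    The interference conditions k d = omega1 d / c_phase pin the singular
    lines near the Brillouin-zone edges x = 0 and x = 2 pi.  Both the
    vacuum-speed (c) and medium-speed (v = c/sqrt(eps)) conventions are
    reported, together with the exclusion half-width the solver uses.
    """
    d = geometry.period
    return {
        "offset_vacuum": omega1 * d / LIGHT_SPEED,
        "offset_medium": omega1 * d / geometry.light_speed_in_medium,
        "exclusion_half_width": LIGHT_CONE_HALF_WIDTH,
    }


def _residual(omega, x, geometry, omega1, inv_tau0, polarization):
    """R(omega) = omega^2 + 2i omega/tau0 - omega1^2 (1 - g F(x, u))."""
    u = np.abs(np.real(omega)) * geometry.period / geometry.light_speed_in_medium
    f = structure_factor_arrays(x, u, polarization)
    return omega**2 + 1j * 2.0 * inv_tau0 * omega - omega1**2 * (
        1.0 - geometry.coupling * f)


def solve_dispersion(geometry: ChainGeometry, omega1: float,
                     inv_tau0: float = 0.0,
                     polarization: str = LONGITUDINAL,
                     k_grid: np.ndarray | None = None,
                     n_points: int = 2001,
                     tol: float = 1e-9,
                     max_iter: int = 200) -> DispersionBranch:
    """Solve the chain dispersion relation for complex omega(k).

    Damped fixed-point iteration seeded at omega = omega1,

        omega_{j+1} = sqrt(omega1^2 (1 - g F(x, u_j)) - 2i omega_j / tau0),

    with a complex-Newton fallback (numerical derivative) for points that
    have not reached a relative residual of ``tol`` after ``max_iter``
    iterations.  Non-converged points are flagged, never dropped.
    """
    if polarization not in (LONGITUDINAL, TRANSVERSE):
        raise InvalidParameterError(f"unknown polarization {polarization!r}")
    if omega1 <= 0:
        raise InvalidParameterError("omega1 must be > 0")
    if k_grid is None:
        k_grid = default_k_grid(geometry, n_points)
    k_grid = np.asarray(k_grid, dtype=float)
    d = geometry.period
    v = geometry.light_speed_in_medium
    g = geometry.coupling
    x_all = k_grid * d

    u1 = omega1 * d / v
    keep = ~_near_light_cone(x_all, u1)
    excluded = k_grid[~keep]
    k = k_grid[keep]
    x = x_all[keep]

    omega = np.full(x.shape, complex(omega1), dtype=complex)
    iters = np.zeros(x.shape, dtype=int)
    active = np.ones(x.shape, dtype=bool)
    for j in range(max_iter):
        u = np.abs(omega[active].real) * d / v
        f = structure_factor_arrays(x[active], u, polarization)
        rhs = omega1**2 * (1.0 - g * f) - 1j * 2.0 * inv_tau0 * omega[active]
        new = np.sqrt(rhs + 0j)
        new = np.where(new.real < 0, -new, new)
        delta = np.abs(new - omega[active])
        omega[active] = new
        iters[active] = j + 1
        still = delta > tol * omega1
        idx = np.flatnonzero(active)
        active[idx[~still]] = False
        if not active.any():
            break

    res = _residual(omega, x, geometry, omega1, inv_tau0, polarization)
    bad = np.abs(res) > tol * omega1**2

    # complex-Newton fallback on the residual, numerical derivative
    h = 1e-7 * omega1
    for i in np.flatnonzero(bad):
        w = omega[i]
        for _ in range(100):
            r0 = _residual(w, x[i], geometry, omega1, inv_tau0, polarization)
            if abs(r0) <= tol * omega1**2:
                break
            dr = (_residual(w + h, x[i], geometry, omega1, inv_tau0, polarization)
                  - _residual(w - h, x[i], geometry, omega1, inv_tau0,
                              polarization)) / (2.0 * h)
            if dr == 0:
                break
            w = w - r0 / dr
        omega[i] = w
        iters[i] += _ + 1

    res = _residual(omega, x, geometry, omega1, inv_tau0, polarization)
    converged = np.abs(res) <= tol * omega1**2

    return DispersionBranch(geometry=geometry, polarization=polarization,
                            omega1=omega1, inv_tau0=inv_tau0,
                            k=k, omega=omega, converged=converged,
                            iterations=iters, excluded_k=excluded)


def group_velocity(branch: DispersionBranch) -> np.ndarray:
    """Group velocity v_g = d(Re omega)/dk [m/s] along the branch.

    Fourth-order (Richardson-refined) central differences in the interior,
    second-order central next to the ends, one-sided at the endpoints.
    Requires at least three consecutive converged points; the result is
    stored on the branch and returned.
    """
    if branch.converged.sum() < 3:
        raise InvalidParameterError("need >= 3 converged points for v_g")
    k = branch.k
    w = branch.omega.real
    n = len(k)
    if n < 3:
        raise InvalidParameterError("branch too short for finite differences")
    h = k[1] - k[0]
    vg = np.empty(n)
    # 4th-order interior
    if n >= 5:
        vg[2:-2] = (8.0 * (w[3:-1] - w[1:-3]) - (w[4:] - w[:-4])) / (12.0 * h)
    # 2nd-order near edges
    vg[1] = (w[2] - w[0]) / (2.0 * h)
    vg[-2] = (w[-1] - w[-3]) / (2.0 * h)
    # one-sided 2nd order at endpoints
    vg[0] = (-3.0 * w[0] + 4.0 * w[1] - w[2]) / (2.0 * h)
    vg[-1] = (3.0 * w[-1] - 4.0 * w[-2] + w[-3]) / (2.0 * h)
    branch.v_g = vg
    return vg


def driven_response(geometry: ChainGeometry, omega1: float, inv_tau0: float,
                    drive: DrivingField) -> complex:
    """Steady-state modal amplitude under an external driving field.

    D_alpha(k, omega) = eps a^3 omega1^2 E0 /
        (omega1^2 - omega^2 - 2i omega/tau0 - omega1^2 g F_alpha(x, u)).

    An exact resonance with zero damping is flagged by returning complex
    infinity rather than raising.
    """
    d = geometry.period
    v = geometry.light_speed_in_medium
    x = drive.k * d
    u = drive.omega * d / v
    sf = structure_factor(x, u, drive.polarization)
    if sf.singular:
        raise LightConeError("driving point lies on the light cone")
    denom = (omega1**2 - drive.omega**2 - 1j * 2.0 * inv_tau0 * drive.omega
             - omega1**2 * geometry.coupling * sf.value)
    numer = geometry.eps * geometry.segment_radius**3 * omega1**2 * drive.amplitude
    if denom == 0:
        return complex(np.inf, np.inf)
    return numer / denom
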