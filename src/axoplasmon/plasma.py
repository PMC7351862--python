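"""Single-segment ionic plasmon quantities.

A finite volume of electrolyte bounded by an insulating membrane supports
collective oscillations of its mobile ions against the neutralizing
background -- ionic surface plasmons, the micrometre/MHz analogue of the
surface plasmons of metallic nanoparticles.  This module collects the
closed-form frequencies and damping rates of a single such segment:

* bulk plasma frequency  omega_p = sqrt(q^2 n / (eps0 m))        (SI)
* multipole surface frequencies  omega_l = omega_p sqrt(l / (eps (2l+1)))
* the dipole (Mie) frequency  omega_1 = omega_p / sqrt(3 eps)
* Ohmic damping  1/tau0 = v/(2 lambda_B) + C v/(2a)  with the mean thermal
  ion speed  v = sqrt(3 kB T / m)
* the damping-red-shifted self-frequency  omega_1' = omega_1
  sqrt(1 - 1/(tau^2 omega_1^2))
* the shape-independent coupling factor  A = V n q^2 / m  of a spheroidal
  segment, equal to eps a^3 omega_1^2 for a sphere.

All interfaces are SI (rad/s, m, kg, C, K).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .constants import BOLTZMANN, VACUUM_PERMITTIVITY


class InvalidParameterError(ValueError):
    """A physical parameter is outside its admissible range."""


@dataclass(frozen=True)
class IonSpecies:
    """An effective charge carrier: charge [C] and mass [kg], both > 0."""

    charge: float
    mass: float

    def __post_init__(self):
        if self.charge <= 0:
            raise InvalidParameterError(f"ion charge must be > 0, got {self.charge}")
        if self.mass <= 0:
            raise InvalidParameterError(f"ion mass must be > 0, got {self.mass}")


@dataclass(frozen=True)
class ElectrolyteMedium:
    """Bulk electrolyte state.

    Parameters
    ----------
    concentration : float
        Ion number density n [1/m^3], >= 0.
    relative_permittivity : float
        Relative permittivity eps of the host (water ~ 80 in the MHz band).
    temperature : float
        Absolute temperature T [K], > 0.
    mean_free_path : float
        Bulk ion mean free path lambda_B [m], > 0.
    """

    concentration: float
    relative_permittivity: float = 80.0
    temperature: float = 300.0
    mean_free_path: float = 1e-9

    def __post_init__(self):
        if self.concentration < 0:
            raise InvalidParameterError("concentration must be >= 0")
        if self.relative_permittivity < 1:
            raise InvalidParameterError("relative permittivity must be >= 1")
        if self.temperature <= 0:
            raise InvalidParameterError("temperature must be > 0")
        if self.mean_free_path <= 0:
            raise InvalidParameterError("mean free path must be > 0")


@dataclass(frozen=True)
class SphericalPlasmonSystem:
    """A spherical electrolyte segment of radius ``radius`` [m].

    ``boundary_scattering_c`` is the order-unity constant weighting
    ion-boundary scattering in the Ohmic rate.
    """

    ion: IonSpecies
    medium: ElectrolyteMedium
    radius: float
    boundary_scattering_c: float = 1.0

    def __post_init__(self):
        if self.radius <= 0:
            raise InvalidParameterError("radius must be > 0")
        if self.boundary_scattering_c <= 0:
            raise InvalidParameterError("boundary scattering constant must be > 0")


@dataclass(frozen=True)
class SpheroidSegment:
    """A spheroidal segment with semiaxes a, b, c [m].

    The per-axis self-frequencies ``self_frequencies`` (rad/s) and damping
    rates ``damping_rates`` (1/s) are phenomenological inputs: elongation
    lowers the frequency of the long-axis dipole mode, but no depolarization
    factors are computed here.
    """

    ion: IonSpecies
    medium: ElectrolyteMedium
    semiaxis_a: float
    semiaxis_b: float
    semiaxis_c: float
    self_frequencies: tuple = field(default=())
    damping_rates: tuple = field(default=())

    def __post_init__(self):
        if min(self.semiaxis_a, self.semiaxis_b, self.semiaxis_c) <= 0:
            raise InvalidParameterError("all semiaxes must be > 0")

    @property
    def volume(self) -> float:
        return 4.0 * math.pi / 3.0 * self.semiaxis_a * self.semiaxis_b * self.semiaxis_c


def plasma_frequency(medium: ElectrolyteMedium, ion: IonSpecies) -> float:
    """Bulk plasma frequency omega_p = sqrt(q^2 n / (eps0 m)) [rad/s]."""
    return math.sqrt(ion.charge**2 * medium.concentration
                     / (VACUUM_PERMITTIVITY * ion.mass))


def mie_frequency(omega_p: float, eps: float) -> float:
    """Dipole surface-plasmon frequency omega_1 = omega_p / sqrt(3 eps)."""
    if eps <= 0:
        raise InvalidParameterError("permittivity must be > 0")
    if omega_p < 0:
        raise InvalidParameterError("omega_p must be >= 0")
    return omega_p / math.sqrt(3.0 * eps)


def multipole_frequency(omega_p: float, eps: float, l: int) -> float:
    """Multipole surface frequency omega_l = omega_p sqrt(l / (eps (2l+1))).

    Increases with l and saturates at omega_p / sqrt(2 eps).
    """
    if l < 1:
        raise InvalidParameterError("multipole order l must be >= 1")
    if eps <= 0:
        raise InvalidParameterError("permittivity must be > 0")
    return omega_p * math.sqrt(l / (eps * (2.0 * l + 1.0)))


def mean_thermal_velocity(medium: ElectrolyteMedium, ion: IonSpecies) -> float:
    """Mean thermal ion speed v = sqrt(3 kB T / m) [m/s] (Boltzmann gas)."""
    return math.sqrt(3.0 * BOLTZMANN * medium.temperature / ion.mass)


def ohmic_damping_rate(system: SphericalPlasmonSystem) -> float:
    """Ohmic scattering rate 1/tau0 = v/(2 lambda_B) + C v/(2a) [1/s].

    First term: bulk ion-ion/solvent scattering; second: boundary scattering
    on the segment wall of radius a.
    """
    v = mean_thermal_velocity(system.medium, system.ion)
    return (v / (2.0 * system.medium.mean_free_path)
            + system.boundary_scattering_c * v / (2.0 * system.radius))


def damped_self_frequency(omega1: float, tau: float) -> tuple[float, bool]:
    """Red-shifted self-frequency omega_1' = omega_1 sqrt(1 - 1/(tau omega_1)^2).

    Returns ``(omega1_prime, overdamped)``.  In the overdamped regime
    (tau * omega_1 < 1) the oscillation frequency is returned as 0.0 with
    the flag set, rather than a complex number.
    """
    if tau <= 0:
        raise InvalidParameterError("tau must be > 0")
    if omega1 < 0:
        raise InvalidParameterError("omega1 must be >= 0")
    x = tau * omega1
    if x < 1.0:
        return 0.0, True
    return omega1 * math.sqrt(1.0 - 1.0 / x**2), False


def spheroid_coupling_factor(segment: SpheroidSegment) -> float:
    """Shape-independent coupling factor A = V n q^2 / m = abc omega_p^2 / 3.

    [m^3 (rad/s)^2].  For a sphere (a = b = c) this equals
    eps * a^3 * omega_1^2.
    """
    omega_p2 = plasma_frequency(segment.medium, segment.ion) ** 2
    abc = segment.semiaxis_a * segment.semiaxis_b * segment.semiaxis_c
    return abc * omega_p2 / 3.0
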