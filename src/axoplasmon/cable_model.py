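"""Passive cable theory: the diffusion baseline the chain model is compared to.

For a membrane cylinder of diameter d the per-length electrical constants are

    C   = c_m * pi * d            [F/m]   membrane capacitance
    1/G = rho1*delta / (pi * d)   [Ohm m] transmembrane leak
    R   = 4 rho / (pi d^2)        [Ohm/m] axial (cytosol) resistance

and the passive conduction velocity scale is

    v_c = lambda / tau = sqrt(G) / (C sqrt(R)),

with length constant lambda = sqrt(1/(G R)) and time constant tau = C/G.
Myelination attenuates both C and G by roughly the same factor (inversely
proportional to sheath thickness), raising v_c by the square root of that
factor; the discrete-diffusion estimate for a myelinated axon with
internodal length l and node length d0 is  v_m = sqrt(l/d0) * v_c.

Inputs are accepted either in SI or, via :func:`CableParameters.from_practical`,
in the mixed units customary in neurophysiology (uF/cm^2, Ohm cm^2, Ohm cm, um).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .plasma import InvalidParameterError


@dataclass(frozen=True)
class CableParameters:
    """SI cable constants.

    membrane_capacitance_per_area : c_m [F/m^2]
    transmembrane_resistivity_times_thickness : rho1*delta [Ohm m^2]
    axial_resistivity : rho [Ohm m]
    diameter : d [m]
    """

    membrane_capacitance_per_area: float
    transmembrane_resistivity_times_thickness: float
    axial_resistivity: float
    diameter: float

    def __post_init__(self):
        for name in ("membrane_capacitance_per_area",
                     "transmembrane_resistivity_times_thickness",
                     "axial_resistivity", "diameter"):
            if getattr(self, name) <= 0:
                raise InvalidParameterError(f"{name} must be > 0")

    @classmethod
    def from_practical(cls, cm_uF_per_cm2: float, rho1delta_ohm_cm2: float,
                       rho_ohm_cm: float, diameter_um: float) -> "CableParameters":
        """Build from the customary mixed units.

        1 uF/cm^2 = 1e-2 F/m^2; 1 Ohm cm^2 = 1e-4 Ohm m^2;
        1 Ohm cm = 1e-2 Ohm m; 1 um = 1e-6 m.
        """
        return cls(cm_uF_per_cm2 * 1e-2, rho1delta_ohm_cm2 * 1e-4,
                   rho_ohm_cm * 1e-2, diameter_um * 1e-6)

    @property
    def capacitance_per_length(self) -> float:
        """C = c_m pi d [F/m]."""
        return self.membrane_capacitance_per_area * math.pi * self.diameter

    @property
    def conductance_per_length(self) -> float:
        """G = pi d / (rho1 delta) [S/m]."""
        return math.pi * self.diameter / self.transmembrane_resistivity_times_thickness

    @property
    def resistance_per_length(self) -> float:
        """R = 4 rho / (pi d^2) [Ohm/m]."""
        return 4.0 * self.axial_resistivity / (math.pi * self.diameter**2)

    @property
    def length_constant(self) -> float:
        """lambda = 1/sqrt(G R) [m]."""
        return 1.0 / math.sqrt(self.conductance_per_length
                               * self.resistance_per_length)

    @property
    def time_constant(self) -> float:
        """tau = C/G [s]."""
        return self.capacitance_per_length / self.conductance_per_length


@dataclass(frozen=True)
class MyelinatedCableParameters:
    """Cable constants plus internodal geometry and myelin attenuation.

    ``myelin_attenuation_factor`` (>= 1) divides both C and G, emulating the
    extra series thickness of the sheath.  ``internodal_length`` l and
    ``node_length`` d0 enter the discrete-diffusion speed-up sqrt(l/d0).
    """

    base: CableParameters
    internodal_length: float
    node_length: float
    myelin_attenuation_factor: float = 1.0

    def __post_init__(self):
        if self.node_length <= 0:
            raise InvalidParameterError("node length must be > 0")
        if self.internodal_length < self.node_length:
            raise InvalidParameterError("internodal length must exceed node length")
        if self.myelin_attenuation_factor < 1:
            raise InvalidParameterError("myelin attenuation factor must be >= 1")


def cable_velocity(p: CableParameters) -> float:
    """Passive velocity scale v_c = sqrt(G)/(C sqrt(R)) [m/s].

    Algebraically identical to lambda/tau; both routes are exposed (the
    identity is exercised in the test suite).  Scales as sqrt(diameter).
    """
    return (math.sqrt(p.conductance_per_length)
            / (p.capacitance_per_length * math.sqrt(p.resistance_per_length)))


def cable_velocity_lambda_tau(p: CableParameters) -> float:
    """v_c via the lambda/tau route (identity cross-check)."""
    return p.length_constant / p.time_constant


def myelinated_velocity(p: MyelinatedCableParameters) -> float:
    """Discrete-diffusion myelinated velocity v_m = sqrt(l/d0) v_c [m/s].

    v_c is evaluated with C and G attenuated by the myelin factor.
    """
    f = p.myelin_attenuation_factor
    b = p.base
    attenuated = CableParameters(
        b.membrane_capacitance_per_area / f,
        b.transmembrane_resistivity_times_thickness * f,
        b.axial_resistivity, b.diameter)
    return math.sqrt(p.internodal_length / p.node_length) * cable_velocity(attenuated)
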