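"""Axon geometry presets and the sphere-chain <-> cord concentration mapping.

The chain model replaces each myelinated sector of the real axon (a thin
cord of radius r wrapped over a length 2a) by a fictitious electrolyte
sphere of radius a.  The ions taking part in the dipole oscillation then
occupy the much smaller cord volume, so the model sphere concentration n
corresponds to a cord concentration

    n' = n * (4/3 pi a^3) / (2 a pi r^2) = (2/3) n (a/r)^2.

Presets are data, shipped as flat key-value config files under
``axoplasmon/presets/``: a myelinated peripheral axon (Schwann-cell
segments 2a = 100 um, Ranvier nodes 0.5/5/10 um) and an unmyelinated
C fibre with periodic lipid-raft Na+ channel clusters (raft length
0.1-0.3 um every 5-10 um), whose segment frequency is red-shifted by
trans-membrane damping.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources

from .config import parse_config
from .constants import AVOGADRO
from .dispersion import ChainGeometry
from .plasma import InvalidParameterError, damped_self_frequency

PRESET_NAMES = ("myelinated_pns", "c_fibre")


@dataclass(frozen=True)
class AxonGeometry:
    """Cord radius r, segment half-length a (segment length 2a), node length.

    The chain period is d = 2a + node_length; ``myelin_thickness`` is absent
    (None) for unmyelinated fibres.
    """

    cord_radius: float
    segment_half_length: float
    node_length: float
    myelin_thickness: float | None = None

    def __post_init__(self):
        if self.cord_radius <= 0 or self.segment_half_length <= 0:
            raise InvalidParameterError("radii must be > 0")
        if self.node_length <= 0:
            raise InvalidParameterError("node length must be > 0")
        if self.cord_radius >= self.segment_half_length:
            raise InvalidParameterError("cord radius must be < segment half-length")

    @property
    def period(self) -> float:
        return 2.0 * self.segment_half_length + self.node_length


@dataclass(frozen=True)
class AxonPreset:
    """A named, dispersion-ready axon parameter set."""

    name: str
    geometry: AxonGeometry
    eps: float
    omega1: float
    tau_omega1: float | None = None  # trans-membrane damping knob (C fibre)
    gate_activation_time: float = 1e-6
    concentration_cord: float | None = None

    def __post_init__(self):
        if self.name not in PRESET_NAMES + ("custom",):
            raise InvalidParameterError(f"unknown preset name {self.name!r}")


def sphere_to_cord_concentration(n: float, a: float, r: float) -> float:
    """Map sphere-model concentration to cord concentration, n' = (2/3) n (a/r)^2."""
    if a <= 0 or r <= 0:
        raise InvalidParameterError("a and r must be > 0")
    return n * (2.0 / 3.0) * (a / r) ** 2


def cord_to_sphere_concentration(n_prime: float, a: float, r: float) -> float:
    """Inverse mapping; exact round-trip with :func:`sphere_to_cord_concentration`."""
    if a <= 0 or r <= 0:
        raise InvalidParameterError("a and r must be > 0")
    return n_prime * 1.5 * (r / a) ** 2


def molar_to_number_density(c_mol_per_litre: float) -> float:
    """mol/L -> ions/m^3 (x N_A x 1e3); 10 mM ~ 6e24 1/m^3."""
    if c_mol_per_litre < 0:
        raise InvalidParameterError("concentration must be >= 0")
    return c_mol_per_litre * AVOGADRO * 1e3


def _load_preset_config(name: str) -> dict:
    with resources.files("axoplasmon.presets").joinpath(f"{name}.cfg").open() as fh:
        return parse_config(fh.read())


def load_preset(name: str) -> AxonPreset:
    """Load a shipped preset by name (``myelinated_pns`` or ``c_fibre``)."""
    if name not in PRESET_NAMES:
        raise InvalidParameterError(
            f"unknown preset {name!r}; available: {', '.join(PRESET_NAMES)}")
    cfg = _load_preset_config(name)
    geom = AxonGeometry(
        cord_radius=float(cfg["geometry.cord_radius_m"]),
        segment_half_length=float(cfg["geometry.segment_half_length_m"]),
        node_length=float(cfg["geometry.node_length_m"]),
        myelin_thickness=(float(cfg["geometry.myelin_thickness_m"])
                          if "geometry.myelin_thickness_m" in cfg else None),
    )
    tau_ratio = (float(cfg["segment.tau_omega1"])
                 if "segment.tau_omega1" in cfg else None)
    return AxonPreset(
        name=name,
        geometry=geom,
        eps=float(cfg["medium.eps"]),
        omega1=float(cfg["segment.omega1_rad_per_s"]),
        tau_omega1=tau_ratio,
        gate_activation_time=float(cfg["node.gate_activation_time_s"]),
        concentration_cord=(float(cfg["medium.n_cord_per_m3"])
                            if "medium.n_cord_per_m3" in cfg else None),
    )


def effective_self_frequency(preset: AxonPreset) -> float:
    """The observable (damping-red-shifted) segment frequency omega_1'.

    Equal to ``preset.omega1`` for undamped presets; for a damped preset
    the red shift omega_1' = omega_1 sqrt(1 - 1/(tau omega_1)^2) applies.
    """
    if preset.tau_omega1 is None:
        return preset.omega1
    tau = preset.tau_omega1 / preset.omega1
    omega1_eff, overdamped = damped_self_frequency(preset.omega1, tau)
    if overdamped:
        raise InvalidParameterError(
            f"preset {preset.name!r} is overdamped (tau*omega1 = {preset.tau_omega1})")
    return omega1_eff


def build_chain(preset: AxonPreset) -> tuple[ChainGeometry, float, float]:
    """Assemble (ChainGeometry, omega1, 1/tau0) for the dispersion solver.

    The returned omega1 is the bare stiffness frequency of the segment
    oscillator; for a damped preset (``tau_omega1`` set, the C-fibre
    regime) the damping rate 1/tau0 = omega1 / tau_omega1 is returned
    alongside, so that the red-shifted observable frequency
    omega_1' = sqrt(omega1^2 - 1/tau0^2) (see
    :func:`effective_self_frequency`) emerges from the solver's uncoupled
    limit rather than being applied twice.
    """
    g = preset.geometry
    if g.node_length <= 0:
        raise InvalidParameterError("node length must be > 0")
    chain = ChainGeometry(segment_radius=g.segment_half_length,
                          period=g.period, eps=preset.eps)
    if preset.tau_omega1 is None:
        return chain, preset.omega1, 0.0
    effective_self_frequency(preset)  # validates the oscillatory regime
    return chain, preset.omega1, preset.omega1 / preset.tau_omega1


def custom_preset(cord_radius: float, segment_half_length: float,
                  node_length: float, eps: float, omega1: float,
                  tau_omega1: float | None = None,
                  gate_activation_time: float = 1e-6) -> AxonPreset:
    """Build an ad-hoc preset with the same validation as shipped ones."""
    geom = AxonGeometry(cord_radius, segment_half_length, node_length)
    return AxonPreset("custom", geom, eps, omega1, tau_omega1,
                      gate_activation_time)
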