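"""Physical constants used throughout the package.

All values are SI.  ``ELECTRON_MASS`` and ``LIGHT_SPEED`` are deliberately
kept at the rounded values conventional in the modelling literature this
package follows (1e4 electron masses for a hydrated ion, c = 3e8 m/s), so
that worked examples reproduce the printed numbers exactly.
"""

VACUUM_PERMITTIVITY = 8.8541878128e-12  # F/m
BOLTZMANN = 1.380649e-23  # J/K
ELECTRON_MASS = 9.1e-31  # kg (rounded convention)
LIGHT_SPEED = 3.0e8  # m/s (rounded convention)
ELEMENTARY_CHARGE = 1.6e-19  # C (rounded convention)
AVOGADRO = 6.02214076e23  # 1/mol
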