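"""Physical constants (SI)."""

import math

#: Vacuum permeability (T m / A).
MU_0 = 4e-7 * math.pi

#: Vacuum permittivity (F / m).
EPS_0 = 8.8541878128e-12

#: Boltzmann constant (J / K).
K_B = 1.380649e-23

#: Standard gravitational acceleration (m / s^2).
G = 9.80665

#: Areal packing fraction of hexagonally close packed discs, pi / (2 sqrt 3).
HCP_FRACTION = math.pi / (2.0 * math.sqrt(3.0))
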