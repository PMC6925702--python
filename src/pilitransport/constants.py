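"""Physical constants used throughout the transport calculations.

All energies are carried in eV and all times in seconds, so the constants
below are the single source of truth for every unit-bearing formula in
:mod:`pilitransport.transport`.  Values are the 2019 SI exact definitions.
"""

from typing import Final

#: Elementary charge, C (exact).
ELEMENTARY_CHARGE: Final[float] = 1.602176634e-19

#: Reduced Planck constant, eV·s (exact).
HBAR_EV_S: Final[float] = 6.582119569e-16

#: Boltzmann constant, eV/K (exact).
BOLTZMANN_EV_PER_K: Final[float] = 8.617333262e-5

#: Ångström in metres.
ANGSTROM: Final[float] = 1e-10
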