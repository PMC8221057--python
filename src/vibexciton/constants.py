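"""Physical constants for transition-dipole coupling in spectroscopic units.

The working unit system is the practical one for vibrational exciton
models: energies/frequencies in wavenumbers (cm^-1), distances in
ångström, transition dipole moments in debye.  The point-dipole coupling
prefactor is derived from CODATA constants at import time rather than
hard-coded, so the unit conversion is auditable.
"""

from __future__ import annotations

import numpy as np
from scipy import constants as _const

#: One debye in SI units (C·m). The debye is defined as 1e-18 statC·cm,
#: i.e. 1e-21/c C·m with c in m/s.
DEBYE_SI: float = 1e-21 / _const.c

#: Molar gas constant, J/(mol·K).
R_GAS: float = _const.R


def dipole_coupling_prefactor() -> float:
    """Vacuum point-dipole coupling constant K in cm^-1·Å^3·D^-2.

    K converts the dimensionless orientation factor times
    ``|mu_i||mu_j| / R^3`` (dipoles in debye, separation in ångström)
    into a coupling energy in wavenumbers:

        J [cm^-1] = K * kappa * |mu_i| |mu_j| / R^3

    with ``K = D^2 / (4 pi eps0 Å^3 h c)`` evaluated in SI and the
    speed of light taken in cm/s for the wavenumber conversion.
    """
    energy_si = DEBYE_SI**2 / (4.0 * np.pi * _const.epsilon_0 * 1e-30)
    return energy_si / (_const.h * _const.c * 100.0)


#: Coupling prefactor, ~5034.12 cm^-1·Å^3·D^-2 in vacuum.
K_DIPOLE: float = dipole_coupling_prefactor()
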