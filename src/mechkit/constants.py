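"""Physical constants and unit conversions, pinned in one place.

All thermochemical energies in this package are kcal/mol, vibrational
frequencies and state-count grids are cm^-1, distances are Angstrom, and
rates are s^-1 (or cm^3 molecule^-1 s^-1 for bimolecular standard-state
conversions).  Every conversion between those systems goes through the
factors below; no other module hard-codes a constant.
"""

import scipy.constants as _sc

#: Boltzmann constant, J/K
K_B = _sc.k
#: Planck constant, J*s
H_PLANCK = _sc.h
#: Speed of light, cm/s (for wavenumber <-> frequency)
C_CM = _sc.c * 100.0
#: Avogadro constant, 1/mol
N_A = _sc.N_A
#: Gas constant in kcal/(mol*K)
R_KCAL = _sc.R / (_sc.calorie * 1000.0)
#: Standard pressure for the TST standard-state factor, Pa (1 bar)
P0_PA = 1.0e5

#: 1 kcal/mol expressed in cm^-1
KCAL_PER_MOL_TO_CM = 349.755

#: k_B*T/(h*c) at T=1 K, i.e. thermal energy in cm^-1 per kelvin
KT_CM_PER_K = K_B / (H_PLANCK * C_CM)


def kcal_to_cm(e_kcal: float) -> float:
    """kcal/mol -> cm^-1."""
    return e_kcal * KCAL_PER_MOL_TO_CM


def cm_to_kcal(e_cm: float) -> float:
    """cm^-1 -> kcal/mol."""
    return e_cm / KCAL_PER_MOL_TO_CM


def thermal_energy_cm(T: float) -> float:
    """k_B*T in cm^-1 at temperature T (K)."""
    return KT_CM_PER_K * T
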