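"""Unit system and conversion constants.

All internal arithmetic uses the LAMMPS "real" convention:

==============  =========================
length          angstrom (A)
time            femtosecond (fs)
mass            atomic mass unit (g/mol)
energy          kcal/mol
force           kcal mol^-1 A^-1
velocity        A/fs
charge          elementary charge e
==============  =========================

Published-facing outputs are converted at the boundary: stress to MPa,
interaction force to pN, membrane tension to mN/m.
"""

import math

#: 1 kcal/mol in J/mol.
KCAL_TO_J = 4184.0

#: Avogadro's number, 1/mol.
N_AVOGADRO = 6.02214076e23

#: Stress conversion: 1 kcal mol^-1 A^-3 expressed in MPa.
#: 4184 J/mol / N_A / (1e-10 m)^3 / 1e6.
KCAL_PER_MOL_A3_TO_MPA = KCAL_TO_J / N_AVOGADRO / 1e-30 / 1e6  # ~6947.7

#: Force conversion: 1 kcal mol^-1 A^-1 expressed in pN.
KCAL_PER_MOL_A_TO_PN = KCAL_TO_J / N_AVOGADRO / 1e-10 * 1e12  # ~69.48

#: Kinetic-energy conversion: 1 amu A^2 fs^-2 expressed in kcal/mol.
#: (1e-3 kg/mol) * (1e-10 m)^2 / (1e-15 s)^2 / 4184 (J/kcal).
AMU_A2_FS2_TO_KCAL_PER_MOL = 1e-3 * 1e10 / KCAL_TO_J  # ~2390.06

#: Boltzmann constant in kcal mol^-1 K^-1.
KB_KCAL_PER_MOL_K = 0.0019872041

#: Coulomb constant in kcal A mol^-1 e^-2 (NAMD value).
COULOMB_CONSTANT = 332.0636

#: Tension identity: 1 MPa * 1 nm = 1 mN/m.
MPA_NM_TO_MN_PER_M = 1.0

#: Strain-rate conversion from fs^-1 to s^-1.
PER_FS_TO_PER_S = 1e15


def thermal_velocity_sigma(mass_amu: float, temperature_k: float) -> float:
    """One-dimensional Maxwell-Boltzmann velocity standard deviation in A/fs."""
    kt = KB_KCAL_PER_MOL_K * temperature_k / AMU_A2_FS2_TO_KCAL_PER_MOL
    return math.sqrt(kt / mass_amu)
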