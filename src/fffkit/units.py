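"""Unit conventions and conversion constants.

All internal computation uses Hartree atomic units (bohr, hartree, electron
mass).  I/O layers convert to/from the conventional units of the field:
angstrom for coordinates, eV or kcal/mol for energies, cm^-1 for vibrational
wavenumbers, degrees for angles, amu for masses.
"""

import math

BOHR_TO_ANGSTROM = 0.52917721
ANGSTROM_TO_BOHR = 1.0 / BOHR_TO_ANGSTROM

HARTREE_TO_EV = 27.211386
EV_TO_HARTREE = 1.0 / HARTREE_TO_EV

# photon wavenumber equivalent of one hartree (E = h c nu~)
HARTREE_TO_INVCM = 219474.63
INVCM_TO_HARTREE = 1.0 / HARTREE_TO_INVCM

KCALMOL_TO_HARTREE = 1.0 / 627.509474
HARTREE_TO_KCALMOL = 627.509474

# one unified atomic mass unit in electron masses
AMU_TO_ME = 1822.888486

DEG_TO_RAD = math.pi / 180.0
RAD_TO_DEG = 180.0 / math.pi

PM_TO_BOHR = 0.01 * ANGSTROM_TO_BOHR


def angular_frequency_to_wavenumber(omega_au: float) -> float:
    """Convert an angular frequency in atomic units to a wavenumber in cm^-1.

    For a harmonic normal mode the transition energy is hbar*omega, which in
    atomic units is numerically ``omega_au`` hartree.
    """
    return omega_au * HARTREE_TO_INVCM
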