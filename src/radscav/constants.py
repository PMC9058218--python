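"""Physical constants (CODATA 2018) and unit helpers.

All interface energies are kJ mol^-1; internal thermodynamic arithmetic is in
J mol^-1. Rate constants are M^-1 s^-1 throughout.
"""

# CODATA 2018 exact values
BOLTZMANN = 1.380649e-23  # J K^-1
PLANCK = 6.62607015e-34  # J s
AVOGADRO = 6.02214076e23  # mol^-1
GAS_CONSTANT = 8.314462618  # J mol^-1 K^-1
SPEED_OF_LIGHT_CM = 2.99792458e10  # cm s^-1

#: J mol^-1 per cm^-1 (h * c * N_A)
WAVENUMBER_TO_J_MOL = PLANCK * SPEED_OF_LIGHT_CM * AVOGADRO

STANDARD_TEMPERATURE = 298.15  # K
STANDARD_PRESSURE = 101325.0  # Pa


def kj_to_j(energy_kj_mol: float) -> float:
    """kJ mol^-1 -> J mol^-1."""
    return energy_kj_mol * 1000.0


def eyring_prefactor(temperature: float) -> float:
    """k_B T / h in s^-1 (6.2124e12 at 298.15 K)."""
    return BOLTZMANN * temperature / PLANCK
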