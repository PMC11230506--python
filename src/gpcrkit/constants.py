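"""Physical constants and unit conventions.

Internal units throughout the package: energies in kcal/mol, lengths in
angstrom (A), time in ps, masses in amu, temperature in K.  The mixed
kcal/mol-amu-A-ps system needs one conversion factor for dynamics:
1 kcal/mol = 418.4 amu*A^2/ps^2.
"""

#: Boltzmann constant, kcal mol^-1 K^-1
KB = 0.0019872041

#: kcal/mol expressed in amu * A^2 / ps^2 (force/acceleration conversion)
KCAL_PER_MOL_TO_AMU_A2_PS2 = 418.4

#: Default simulation temperature (NVT), K
DEFAULT_TEMPERATURE = 310.0


def kbt(temperature: float = DEFAULT_TEMPERATURE) -> float:
    """Thermal energy k_B*T in kcal/mol."""
    return KB * temperature
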