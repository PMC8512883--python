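"""Physical constants and unit conventions.

Package-wide units: lengths in nm, energies in kJ/mol, angles in radians
internally (degrees only at presentation), temperatures in K.
"""

#: Gas constant, kJ mol^-1 K^-1.
R_GAS = 8.3145e-3

#: Electric conversion factor f = 1/(4 pi eps0), kJ mol^-1 nm e^-2.
COULOMB_CONSTANT = 138.935458

#: Default simulation temperature, K.
DEFAULT_TEMPERATURE = 300.0


def kT(temperature: float = DEFAULT_TEMPERATURE) -> float:
    """Thermal energy R*T in kJ/mol (molar convention, so k_B == R here)."""
    return R_GAS * temperature
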