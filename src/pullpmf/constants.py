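"""Physical constants and unit conversions.

Internal canonical units: length Å, time ps, energy kcal/mol, force
kcal/mol/Å, temperature K.  Forces are converted to pN only at reporting
boundaries.
"""

#: Boltzmann constant, kcal/mol/K.
KB_KCAL_MOL_K = 0.0019872041

#: 1 kcal/mol/Å expressed in piconewton.
PN_PER_KCAL_MOL_ANG = 69.4786


def kT(temperature: float) -> float:
    """Thermal energy k_B*T in kcal/mol for a temperature in kelvin."""
    return KB_KCAL_MOL_K * temperature


def force_to_pN(force_kcal_mol_ang):
    """Convert a force (kcal/mol/Å) to pN; array-safe."""
    return force_kcal_mol_ang * PN_PER_KCAL_MOL_ANG
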