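"""Physical constants and unit conventions.

Units throughout the package: energies in kcal/mol, lengths in angstrom,
masses in amu (g/mol), times in ps, temperatures in Kelvin.  With this
choice one kcal/mol equals exactly 418.4 amu A^2/ps^2, which is the only
conversion molecular dynamics needs.
"""

#: Boltzmann constant, kcal/mol/K (Amber convention).
KB = 0.0019872041

#: 1 kcal/mol expressed in amu * A^2 / ps^2 (exact: 4184 J/mol / 10 J/mol).
KCAL_PER_MOL_TO_MD = 418.4

#: Coulomb constant q_i q_j / r prefactor for e-charges, A, kcal/mol.
COULOMB_CONSTANT = 332.0637


def thermal_energy(temperature: float) -> float:
    """kT in kcal/mol for a temperature in Kelvin."""
    return KB * temperature


def temperature_for_kt(kt: float) -> float:
    """Temperature (K) at which the thermal energy equals ``kt`` kcal/mol.

    Convenient for working in natural units (kT = 1).
    """
    return kt / KB
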