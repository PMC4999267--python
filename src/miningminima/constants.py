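"""Physical constants and unit conventions.

All energies are kcal/mol, lengths Å, angles degrees at I/O boundaries and
radians internally, temperatures K, charges in units of the elementary charge.
"""

#: Gas constant in kcal/(mol K).
R_KCAL: float = 1.9872e-3

#: Coulomb constant in kcal Å / (mol e^2).
COULOMB_CONSTANT: float = 332.06

#: Avogadro's number, 1/mol.
AVOGADRO: float = 6.02214076e23

#: Default temperature (K) used throughout; the temperature of the
#: underlying simulations and of every printed affinity conversion.
DEFAULT_TEMPERATURE: float = 300.0


def rt(temperature: float = DEFAULT_TEMPERATURE) -> float:
    """Thermal energy RT in kcal/mol."""
    return R_KCAL * temperature


def standard_concentration_per_A3(c_molar: float = 1.0) -> float:
    """Standard concentration C° converted to molecules/Å^3.

    1 mol/L = N_A * 1e-27 molecules per Å^3.
    """
    return AVOGADRO * c_molar * 1e-27
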