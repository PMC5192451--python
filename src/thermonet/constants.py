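"""Physical constants shared across the package.

All energies are kJ/mol, temperatures K, concentrations mol/L and
membrane potentials V throughout the package.
"""

#: Molar gas constant R in kJ mol^-1 K^-1 (CODATA 2018).
GAS_CONSTANT: float = 8.31446261815324e-3

#: Faraday constant in kJ mol^-1 V^-1.
FARADAY: float = 96.485

#: Extended Debye-Hueckel constant A in L^1/2 mol^-1/2 (25 degC, 1 bar).
DEBYE_HUECKEL_A: float = 0.510651

#: Extended Debye-Hueckel constant B in L^1/2 mol^-1/2.
DEBYE_HUECKEL_B: float = 1.6

#: Default (standard biological) temperature, K.
DEFAULT_TEMPERATURE: float = 298.15

#: Validity range of the extended Debye-Hueckel equation, mol/L.
IONIC_STRENGTH_VALIDITY: tuple[float, float] = (0.005, 0.25)

#: Reactant names treated as water: activity fixed at 1 in concentration
#: terms, while its formation energy still enters standard reaction sums.
WATER_NAMES: frozenset[str] = frozenset({"H2O", "h2o", "H2o", "water", "Water", "WATER"})

#: Tokens recognised as free protons; reactions are stored proton-free
#: because pH is held constant by the transform.
PROTON_NAMES: frozenset[str] = frozenset({"H+", "h+", "H⁺", "H(+)", "proton", "H"})
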