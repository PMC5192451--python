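"""Bundled yeast-glycolysis fixture and its published reference values.

The fixture carries the species table (formation energy, charge,
hydrogen count per protonation state; NAD/NADH on the NAD-as-zero
reference convention), the ten glycolysis reactions as equation
strings, the physiological conditions they are evaluated under
(cytosolic pH 7, ionic strength 0.15 M, 298.15 K) and the published
reactant- and reaction-level transformed energies those inputs
reproduce.

One published value is internally inconsistent: the PGK entry prints
+8.16 kJ/mol, but the stoichiometric sum over the published formation
energies gives -8.16 kJ/mol (the magnitude is exact, the printed sign
is not).  :data:`GLYCOLYSIS_DG0_PRINTED` keeps the printed value;
:data:`SIGN_DISCREPANCIES` names the affected reaction so tests and
users can compare magnitudes there.
"""

from __future__ import annotations

import io

from . import _data
from .core import Conditions, Reactant, Reaction, TransformedEnergy, reactant_energy
from .io import read_reaction_table, read_species_table

__all__ = [
    "yeast_conditions",
    "glycolysis_species",
    "glycolysis_reactions",
    "glycolysis_energies",
    "glycolysis_dg0",
    "GLYCOLYSIS_DFG0_PRINTED",
    "GLYCOLYSIS_DG0_PRINTED",
    "SIGN_DISCREPANCIES",
]

#: Published reactant-level transformed formation energies [kJ/mol]
#: at pH 7, I = 0.15 M, 298.15 K (rounded to two decimals as printed).
GLYCOLYSIS_DFG0_PRINTED: dict[str, float] = {
    "3-Phospho-glyceroyl phosphate": -2206.35,
    "2-Phospho-glycerate": -1341.51,
    "3-Phospho-glycerate": -1347.41,
    "ADP": -1425.17,
    "ATP": -2292.28,
    "Glycerone phosphate": -1095.82,
    "Fructose 6-phosphate": -1316.55,
    "Fructose 1,6-bisphosphate": -2206.14,
    "Glyceraldehyde 3-phosphate": -1088.16,
    "Glucose": -428.06,
    "Glucose 6-phosphate": -1319.75,
    "H2O": -155.88,
    "NAD": 1056.29,
    "NADH": 1117.50,
    "Phosphoenolpyruvate": -1189.04,
    "Pi": -1059.30,
    "Pyruvate": -351.01,
}

#: Published per-reaction standard transformed energies [kJ/mol].
GLYCOLYSIS_DG0_PRINTED: dict[str, float] = {
    "HEX1": -24.58,
    "PGI": 3.20,
    "PFK": -22.48,
    "FBA": 22.15,
    "TPI": 7.66,
    "GAPD": 2.32,
    "PGK": 8.16,
    "PGM": 5.90,
    "ENO": -3.41,
    "PYK": -29.08,
}

#: Reactions whose published value matches the stoichiometric sum in
#: magnitude only (printed sign inconsistent with the formation table).
SIGN_DISCREPANCIES: frozenset[str] = frozenset({"PGK"})


def yeast_conditions() -> Conditions:
    """Cytosolic conditions of the fixture: pH 7, I = 0.15 M, 298.15 K."""
    return Conditions(ph=7.0, ionic_strength=0.15, temperature=298.15,
                      compartment_id="cytosol")


def glycolysis_species() -> dict[str, Reactant]:
    """The 17 reactants (32 species rows) of the glycolysis fixture."""
    return read_species_table(io.StringIO(_data.data_text("glycolysis_species.tsv")))


def glycolysis_reactions() -> list[Reaction]:
    """The ten glycolysis reactions, all reversible."""
    return read_reaction_table(io.StringIO(_data.data_text("glycolysis_reactions.tsv")))


def glycolysis_energies(conditions: Conditions | None = None) -> dict[str, TransformedEnergy]:
    """Reactant-level transformed energies of the fixture."""
    conditions = conditions or yeast_conditions()
    return {
        name: reactant_energy(reactant, conditions)
        for name, reactant in glycolysis_species().items()
    }


def glycolysis_dg0(conditions: Conditions | None = None) -> dict[str, float]:
    """Per-reaction standard transformed energies of the fixture."""
    from .core import reaction_standard_dg

    energies = glycolysis_energies(conditions)
    return {r.id: reaction_standard_dg(r, energies) for r in glycolysis_reactions()}
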