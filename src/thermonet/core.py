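"""Transformed Gibbs energies of formation and reaction.

Biochemical reactants (ATP, Pi, ...) are pools of protonation states
("species") at internal equilibrium.  Starting from each species'
standard Gibbs energy of formation, charge and hydrogen count, this
module applies the Legendre transform to specified pH and the extended
Debye-Hueckel activity correction to specified ionic strength, merges
the resulting species-level energies into a single reactant-level
energy, and sums reactant energies stoichiometrically into standard and
concentration-dependent reaction Gibbs energies.

The transform of a species i with formation energy G_i, charge z_i and
N_H hydrogens at pH, ionic strength I and temperature T is

    G_i' = G_i - N_H * R*T*ln(10^-pH)
               - R*T*ln(10)*A * (z_i^2 - N_H) * sqrt(I) / (1 + B*sqrt(I))

with Debye-Hueckel constants A, B.  At 298.15 K the coefficient
R*T*ln(10)*A equals 2.91480 kJ/mol; it is recomputed from A and T so
other temperatures are supported.  The reactant-level energy of a
pseudoisomer group is the log-sum-exp merge

    G_j' = -R*T * ln( sum_i exp(-G_i'/(R*T)) )

which is always at or below the lowest species energy.
"""

from __future__ import annotations

import enum
import math
import warnings
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field

from scipy.special import logsumexp

from .constants import (
    DEBYE_HUECKEL_A,
    DEBYE_HUECKEL_B,
    DEFAULT_TEMPERATURE,
    GAS_CONSTANT,
    IONIC_STRENGTH_VALIDITY,
    WATER_NAMES,
)

__all__ = [
    "Conditions",
    "Species",
    "Reactant",
    "TransformedEnergy",
    "Directionality",
    "Reaction",
    "log_activity_coefficient",
    "transform_species",
    "merge_pseudoisomers",
    "reactant_energy",
    "reaction_standard_dg",
    "reaction_dg",
]


class ConditionsWarning(UserWarning):
    """Conditions outside the stated validity range of a correction."""


@dataclass(frozen=True)
class Conditions:
    """pH, ionic strength [mol/L] and temperature [K] of a compartment.

    A transformed energy is meaningless without these, so every
    :class:`TransformedEnergy` carries the conditions it was computed
    under.  Ionic strengths outside the Debye-Hueckel validity range
    (0.005-0.25 M) are recorded in :attr:`warnings` and additionally
    emitted as a :class:`ConditionsWarning`; the value is still used.
    """

    ph: float = 7.0
    ionic_strength: float = 0.15
    temperature: float = DEFAULT_TEMPERATURE
    compartment_id: str = "cytosol"
    warnings: tuple[str, ...] = field(default=(), compare=False)

    def __post_init__(self) -> None:
        if self.ionic_strength < 0:
            raise ValueError(f"ionic_strength must be >= 0, got {self.ionic_strength}")
        if self.temperature <= 0:
            raise ValueError(f"temperature must be > 0 K, got {self.temperature}")
        notes = []
        lo, hi = IONIC_STRENGTH_VALIDITY
        if self.ionic_strength != 0 and not (lo <= self.ionic_strength <= hi):
            msg = (
                f"ionic strength {self.ionic_strength} M is outside the "
                f"Debye-Hueckel validity range [{lo}, {hi}] M"
            )
            notes.append(msg)
            warnings.warn(msg, ConditionsWarning, stacklevel=2)
        object.__setattr__(self, "warnings", tuple(notes))

    @property
    def rt(self) -> float:
        """R*T in kJ/mol."""
        return GAS_CONSTANT * self.temperature

    def same_state(self, other: "Conditions") -> bool:
        """True if pH, ionic strength and temperature are identical."""
        return (
            self.ph == other.ph
            and self.ionic_strength == other.ionic_strength
            and self.temperature == other.temperature
        )


@dataclass(frozen=True)
class Species:
    """One protonation state of a biochemical reactant.

    ``dfg0`` is the standard Gibbs energy of formation in kJ/mol (it may
    be a relative value under a reference convention, e.g. NAD set to 0;
    ``reference_group`` tags the convention so redox pairs cannot mix
    conventions unnoticed), ``charge`` the ionic charge z and
    ``n_hydrogen`` the number of hydrogen atoms N_H.
    """

    name: str
    dfg0: float
    charge: int
    n_hydrogen: int
    reference_group: str = ""

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("species name must be non-empty")
        if self.n_hydrogen < 0:
            raise ValueError(f"{self.name}: n_hydrogen must be >= 0")


@dataclass(frozen=True)
class Reactant:
    """A pseudoisomer group: the protonation states of one reactant."""

    name: str
    species: tuple[Species, ...]
    compartment_id: str = "cytosol"

    def __post_init__(self) -> None:
        if not self.species:
            raise ValueError(f"reactant {self.name!r} needs at least one species")
        names = [s.name for s in self.species]
        if len(set(names)) != len(names):
            raise ValueError(f"reactant {self.name!r} has duplicate species names")


class EnergyLevel(str, enum.Enum):
    SPECIES = "species"
    REACTANT = "reactant"


@dataclass(frozen=True)
class TransformedEnergy:
    """A transformed standard formation energy [kJ/mol] with its conditions."""

    value: float
    conditions: Conditions
    level: EnergyLevel = EnergyLevel.SPECIES


class Directionality(str, enum.Enum):
    FORWARD_ONLY = "forward_only"
    BACKWARD_ONLY = "backward_only"
    REVERSIBLE = "reversible"


@dataclass(frozen=True)
class Reaction:
    """Stoichiometry over reactants; negative coefficients are substrates."""

    id: str
    stoichiometry: Mapping[str, float]
    directionality: Directionality = Directionality.REVERSIBLE
    is_transport: bool = False

    def __post_init__(self) -> None:
        stoich = {k: float(v) for k, v in self.stoichiometry.items() if v != 0}
        if not stoich:
            raise ValueError(f"reaction {self.id!r} has no nonzero coefficients")
        object.__setattr__(self, "stoichiometry", stoich)

    def reversed(self) -> "Reaction":
        flip = {
            Directionality.FORWARD_ONLY: Directionality.BACKWARD_ONLY,
            Directionality.BACKWARD_ONLY: Directionality.FORWARD_ONLY,
            Directionality.REVERSIBLE: Directionality.REVERSIBLE,
        }
        return Reaction(
            id=self.id,
            stoichiometry={k: -v for k, v in self.stoichiometry.items()},
            directionality=flip[self.directionality],
            is_transport=self.is_transport,
        )


def log_activity_coefficient(charge: int, conditions: Conditions) -> float:
    """log10 activity coefficient from the extended Debye-Hueckel equation.

    Returns ``-A * z^2 * sqrt(I) / (1 + B * sqrt(I))``; exactly 0 for
    uncharged species or zero ionic strength.
    """
    if charge == 0 or conditions.ionic_strength == 0:
        return 0.0
    sqrt_i = math.sqrt(conditions.ionic_strength)
    return -DEBYE_HUECKEL_A * charge * charge * sqrt_i / (1.0 + DEBYE_HUECKEL_B * sqrt_i)


def _ionic_coefficient(temperature: float) -> float:
    # R*T*ln(10)*A; equals 2.91480 kJ/mol at 298.15 K.
    return GAS_CONSTANT * temperature * math.log(10.0) * DEBYE_HUECKEL_A


def transform_species(species: Species, conditions: Conditions) -> TransformedEnergy:
    """Standard transformed formation energy of one species at pH, I, T."""
    rt = conditions.rt
    sqrt_i = math.sqrt(conditions.ionic_strength)
    ph_term = species.n_hydrogen * rt * math.log(10.0 ** -conditions.ph)
    ionic_term = (
        _ionic_coefficient(conditions.temperature)
        * (species.charge**2 - species.n_hydrogen)
        * sqrt_i
        / (1.0 + DEBYE_HUECKEL_B * sqrt_i)
    )
    value = species.dfg0 - ph_term - ionic_term
    return TransformedEnergy(value=value, conditions=conditions, level=EnergyLevel.SPECIES)


def merge_pseudoisomers(
    energies: Sequence[TransformedEnergy] | Iterable[TransformedEnergy],
    conditions: Conditions,
) -> TransformedEnergy:
    """Merge species-level energies into the reactant-level energy.

    Implements ``G' = -R*T*ln(sum_i exp(-G_i'/(R*T)))`` with a
    numerically stable log-sum-exp; the result is at or below the lowest
    input energy.  All inputs must share ``conditions``.
    """
    energies = list(energies)
    if not energies:
        raise ValueError("need at least one species energy to merge")
    for e in energies:
        if not e.conditions.same_state(conditions):
            raise ValueError(
                "cannot merge energies computed under different conditions: "
                f"{e.conditions} vs {conditions}"
            )
    rt = conditions.rt
    value = -rt * logsumexp([-e.value / rt for e in energies])
    return TransformedEnergy(value=float(value), conditions=conditions, level=EnergyLevel.REACTANT)


def reactant_energy(reactant: Reactant, conditions: Conditions) -> TransformedEnergy:
    """Transform every species of a reactant, then merge the group."""
    return merge_pseudoisomers(
        [transform_species(s, conditions) for s in reactant.species], conditions
    )


def reaction_standard_dg(
    reaction: Reaction,
    energies: Mapping[str, TransformedEnergy],
) -> float:
    """Standard transformed reaction energy: the stoichiometric sum S . G'.

    Water participates here with its own formation energy (its atoms are
    accounted for in the standard term even though its activity is fixed
    at 1 in the concentration term).
    """
    reference: Conditions | None = None
    total = 0.0
    for name, coeff in reaction.stoichiometry.items():
        if name not in energies:
            raise KeyError(
                f"reaction {reaction.id!r}: no transformed energy for reactant {name!r}"
            )
        energy = energies[name]
        if reference is None:
            reference = energy.conditions
        elif not energy.conditions.same_state(reference):
            raise ValueError(
                f"reaction {reaction.id!r}: reactant {name!r} energy was computed "
                "under different conditions than the others"
            )
        total += coeff * energy.value
    return total


def reaction_dg(
    reaction: Reaction,
    dg0: float,
    concentrations: Mapping[str, float],
    conditions: Conditions,
) -> float:
    """Concentration-dependent reaction energy dG' = dG'0 + RT * S . ln(c).

    Water activity is fixed at 1 (excluded from the log term) and
    protons never appear in stored reactions, so only the remaining
    reactants need concentrations, all of which must be positive.
    """
    rt = conditions.rt
    log_q = 0.0
    for name, coeff in reaction.stoichiometry.items():
        if name in WATER_NAMES:
            continue
        if name not in concentrations:
            raise KeyError(f"reaction {reaction.id!r}: missing concentration for {name!r}")
        c = concentrations[name]
        if c <= 0:
            raise ValueError(
                f"reaction {reaction.id!r}: concentration of {name!r} must be positive, got {c}"
            )
        log_q += coeff * math.log(c)
    return dg0 + rt * log_q
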