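"""Gibbs energies of transmembrane transport reactions.

A transport reaction is split into the chemical part happening inside a
compartment and the translocation part; their standard transformed
energies add:

    dG'0_total = dG'0_chemical + dG_psi + dG_pH

The membrane-potential term is n*F*dPsi for n net charges moved across
a potential difference dPsi, and the pH term combines each transported
species' compartment-specific transformed formation energy with a
-2.3*R*T * sum_i s_i * N_H(i) * pH_i proton correction.

Sign convention (documented, since conventions differ between tools):
stoichiometric coefficients and dPsi are oriented destination-minus-
origin: a species leaving the origin compartment carries s_i = -1 and
the same species arriving at the destination s_i = +1, while dPsi is
the destination potential minus the origin potential.  A positive
charge moving down the potential (dPsi < 0) therefore contributes a
negative dG_psi in the forward direction.
"""

from __future__ import annotations

import math
from collections.abc import Mapping
from dataclasses import dataclass

from .constants import FARADAY, GAS_CONSTANT
from .core import Conditions, Species, transform_species

__all__ = [
    "TransportedSpecies",
    "TransportSpec",
    "membrane_potential_term",
    "delta_ph_term",
    "transport_term",
    "transport_reaction_dg0",
]


@dataclass(frozen=True)
class TransportedSpecies:
    """One side of a translocation: a species, its signed coefficient
    (destination-minus-origin orientation) and the compartment it sits in."""

    species: Species
    coefficient: float
    compartment_id: str


@dataclass(frozen=True)
class TransportSpec:
    """Charge and species movements of one transport reaction.

    ``net_charge_translocated`` is the net charge n moved to the
    destination side; ``delta_psi`` the membrane potential [V],
    destination minus origin.
    """

    net_charge_translocated: int
    delta_psi: float
    transported: tuple[TransportedSpecies, ...] = ()

    def __post_init__(self) -> None:
        if not self.transported and self.net_charge_translocated == 0:
            raise ValueError(
                "transport spec must move at least one species or a net charge"
            )

    def reversed(self) -> "TransportSpec":
        """Run the transport the other way: negate n and every s_i.

        dPsi is a property of the membrane (fixed compartment-label
        orientation), so it is kept; the reversed charge movement then
        negates n*F*dPsi, and the negated coefficients negate the pH
        term, making the whole transport term antisymmetric.
        """
        return TransportSpec(
            net_charge_translocated=-self.net_charge_translocated,
            delta_psi=self.delta_psi,
            transported=tuple(
                TransportedSpecies(t.species, -t.coefficient, t.compartment_id)
                for t in self.transported
            ),
        )


def membrane_potential_term(n: int, delta_psi: float) -> float:
    """Electrical work n*F*dPsi [kJ/mol] of moving n charges across dPsi [V]."""
    return n * FARADAY * delta_psi


def delta_ph_term(spec: TransportSpec, conditions: Mapping[str, Conditions]) -> float:
    """pH-gradient contribution [kJ/mol] of the translocation.

    Each transported species contributes its own compartment-specific
    transformed formation energy (signed by s_i) plus the proton
    correction -2.3*R*T_comp * s_i * N_H * pH_comp evaluated in its own
    compartment.  When both compartments share identical conditions and
    the species sets cancel pairwise, the term is exactly zero.
    """
    total = 0.0
    for entry in spec.transported:
        if entry.compartment_id not in conditions:
            raise KeyError(
                f"no conditions for compartment {entry.compartment_id!r} "
                f"(transported species {entry.species.name!r})"
            )
        cond = conditions[entry.compartment_id]
        energy = transform_species(entry.species, cond).value
        proton = (
            2.3
            * GAS_CONSTANT
            * cond.temperature
            * entry.species.n_hydrogen
            * cond.ph
        )
        total += entry.coefficient * (energy - proton)
    return total


def transport_term(spec: TransportSpec, conditions: Mapping[str, Conditions]) -> float:
    """dG_psi + dG_pH of the translocation alone."""
    return membrane_potential_term(spec.net_charge_translocated, spec.delta_psi) + (
        delta_ph_term(spec, conditions) if spec.transported else 0.0
    )


def transport_reaction_dg0(
    compartment_dg0: float,
    spec: TransportSpec,
    conditions: Mapping[str, Conditions],
) -> float:
    """Total standard transformed energy: chemical part + transport part."""
    return compartment_dg0 + transport_term(spec, conditions)
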