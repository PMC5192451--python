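"""Model-curation passes applied before NET analysis.

Two standard clean-ups for thermodynamic analysis of imported models:

* opposite-direction isozyme pairs — two fixed-direction reactions with
  exactly mirrored stoichiometry — are merged into one reversible
  reaction.  Left separate, the only state satisfying both sign
  constraints simultaneously is equilibrium (dG' = 0 for both), which
  silently pins the network to it.

* aqueous CO2 species (dissolved CO2, bicarbonate, carbonate, carbonic
  acid) are pooled into a single reactant "CO2tot", with water added to
  the opposite side to rebalance oxygen atoms.  Applied only to the
  species names the caller tags.
"""

from __future__ import annotations

from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field, replace

from .core import Directionality, Reaction

__all__ = ["CurationReport", "lump_opposite_isozymes", "pool_co2_species"]

#: Oxygen-atom counts of the conventional aqueous CO2 pool members,
#: relative to which water rebalancing is computed (CO2tot is referenced
#: as the 2-oxygen dissolved form).
DEFAULT_CO2_OXYGEN: dict[str, int] = {
    "CO2": 2,
    "HCO3": 3,
    "HCO3-": 3,
    "CO3": 3,
    "CO3 2-": 3,
    "H2CO3": 3,
}


@dataclass
class CurationReport:
    lumped_pairs: list[tuple[str, str, str]] = field(default_factory=list)
    pooled_reactions: list[str] = field(default_factory=list)

    def summary(self) -> str:
        lines = []
        for a, b, merged in self.lumped_pairs:
            lines.append(f"lumped opposite-direction pair {a} / {b} -> {merged} (reversible)")
        for rid in self.pooled_reactions:
            lines.append(f"pooled CO2 species into CO2tot in {rid} (water rebalanced)")
        return "\n".join(lines) if lines else "no curation changes"


def _mirrored(a: Reaction, b: Reaction) -> bool:
    if set(a.stoichiometry) != set(b.stoichiometry):
        return False
    return all(b.stoichiometry[k] == -v for k, v in a.stoichiometry.items())


def lump_opposite_isozymes(
    reactions: Sequence[Reaction],
) -> tuple[list[Reaction], CurationReport]:
    """Merge fixed-direction reaction pairs with mirrored stoichiometry.

    The merged reaction keeps the first pair member's stoichiometry and
    id (suffixed "_lumped") and becomes reversible.  Reversible
    reactions and non-mirrored pairs pass through untouched.
    """
    report = CurationReport()
    out: list[Reaction] = []
    consumed: set[str] = set()
    fixed = [r for r in reactions if r.directionality is not Directionality.REVERSIBLE]
    for i, a in enumerate(fixed):
        if a.id in consumed:
            continue
        for b in fixed[i + 1 :]:
            if b.id in consumed:
                continue
            # same fixed direction over mirrored stoichiometry, or opposite
            # fixed directions over identical stoichiometry: net directions clash
            opposite = (
                (a.directionality is b.directionality and _mirrored(a, b))
                or (a.directionality is not b.directionality
                    and a.stoichiometry == b.stoichiometry)
            )
            if opposite:
                merged_id = f"{a.id}_lumped"
                out.append(
                    Reaction(
                        id=merged_id,
                        stoichiometry=dict(a.stoichiometry),
                        directionality=Directionality.REVERSIBLE,
                    )
                )
                consumed.update({a.id, b.id})
                report.lumped_pairs.append((a.id, b.id, merged_id))
                break
    for r in reactions:
        if r.id not in consumed:
            out.append(r)
    # keep input order for untouched reactions, merged ones first
    order = {r.id: i for i, r in enumerate(reactions)}
    out.sort(key=lambda r: order.get(r.id, order.get(r.id.removesuffix("_lumped"), 0)))
    return out, report


def pool_co2_species(
    reactions: Sequence[Reaction],
    tagged: Mapping[str, int] | Sequence[str] | None = None,
    *,
    pool_name: str = "CO2tot",
    water_name: str = "H2O",
) -> tuple[list[Reaction], CurationReport]:
    """Replace tagged CO2-pool species by CO2tot, rebalancing oxygen with water.

    ``tagged`` maps species name -> oxygen count (or is a sequence of
    names looked up in :data:`DEFAULT_CO2_OXYGEN`).  Untagged models
    pass through unchanged.
    """
    if tagged is None:
        tagged = {}
    if not isinstance(tagged, Mapping):
        unknown = [n for n in tagged if n not in DEFAULT_CO2_OXYGEN]
        if unknown:
            raise KeyError(f"no oxygen count known for species: {', '.join(unknown)}")
        tagged = {n: DEFAULT_CO2_OXYGEN[n] for n in tagged}

    report = CurationReport()
    out: list[Reaction] = []
    for r in reactions:
        if not any(name in tagged for name in r.stoichiometry):
            out.append(r)
            continue
        stoich: dict[str, float] = {}
        water_adjust = 0.0
        for name, coeff in r.stoichiometry.items():
            if name in tagged:
                stoich[pool_name] = stoich.get(pool_name, 0.0) + coeff
                water_adjust += coeff * (tagged[name] - 2)  # CO2tot carries 2 oxygens
            else:
                stoich[name] = stoich.get(name, 0.0) + coeff
        if water_adjust:
            stoich[water_name] = stoich.get(water_name, 0.0) + water_adjust
        out.append(replace(r, stoichiometry=stoich))
        report.pooled_reactions.append(r.id)
    return out, report
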