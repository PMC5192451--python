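"""Deterministic generator of small test networks with known status.

Feasible networks are built concentration-first: an interior
log-concentration point is sampled inside the bounds, sign-constrained
reactions then get a standard energy chosen so the sampled point drives
them as required with a clear margin (2-15 kJ/mol), and reversible
reactions get energies sampled freely.  The sampled point is therefore
a feasibility witness by construction.

Infeasible networks start from a feasible one and plant a single
over-constrained forward reaction: a unimolecular S -> P step whose
standard energy exceeds what even the extreme corner of the bounds box
(substrate at c_max, product at c_min) could pull below zero, by a
25 kJ/mol margin.  No concentration assignment can rescue it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import GAS_CONSTANT
from .core import Conditions, Directionality, Reaction

__all__ = ["ToyNetworkSpec", "ToyNetwork", "generate_toy_network"]

_FORWARD_MARGIN = (2.0, 15.0)  # kJ/mol below the -eps constraint at the witness
_INFEASIBLE_MARGIN = 25.0  # kJ/mol beyond the best achievable corner


@dataclass(frozen=True)
class ToyNetworkSpec:
    """What to generate: sizes, seed, target status and sampling ranges."""

    n_metabolites: int = 4
    n_reactions: int = 3
    seed: int = 0
    target: str = "feasible"  # feasible | infeasible
    dg0_range: tuple[float, float] = (-30.0, 30.0)
    bounds_range: tuple[float, float] = (1e-6, 5e-2)
    fraction_constrained: float = 0.5

    def __post_init__(self) -> None:
        if self.n_metabolites < 2:
            raise ValueError("need at least 2 metabolites")
        if self.n_reactions < 1:
            raise ValueError("need at least 1 reaction")
        if self.target not in ("feasible", "infeasible"):
            raise ValueError(f"unknown target status {self.target!r}")
        if self.target == "infeasible" and self.fraction_constrained == 0:
            raise ValueError(
                "an infeasible network needs at least one sign-constrained reaction"
            )


@dataclass(frozen=True)
class ToyNetwork:
    reactions: tuple[Reaction, ...]
    dg0: dict[str, float]
    bounds: dict[str, tuple[float, float]]
    conditions: Conditions
    expected_status: str
    witness_log_concentrations: dict[str, float] = field(default_factory=dict)


def generate_toy_network(spec: ToyNetworkSpec) -> ToyNetwork:
    """Generate a network whose feasibility status is known by construction."""
    rng = np.random.default_rng(spec.seed)
    conditions = Conditions()
    rt = GAS_CONSTANT * conditions.temperature
    names = [f"M{i + 1}" for i in range(spec.n_metabolites)]

    lo, hi = spec.bounds_range
    log_lo, log_hi = np.log(lo), np.log(hi)
    # interior witness point, kept off the box faces
    shrink = 0.1 * (log_hi - log_lo)
    witness = rng.uniform(log_lo + shrink, log_hi - shrink, size=spec.n_metabolites)

    reactions: list[Reaction] = []
    dg0: dict[str, float] = {}
    for j in range(spec.n_reactions):
        n_sub = int(rng.integers(1, 3))
        n_prod = int(rng.integers(1, 3))
        picks = rng.choice(spec.n_metabolites, size=min(n_sub + n_prod, spec.n_metabolites),
                           replace=False)
        subs, prods = picks[:n_sub], picks[n_sub:]
        if len(prods) == 0:
            subs, prods = picks[:-1], picks[-1:]
        stoich = {names[i]: -1.0 for i in subs}
        stoich.update({names[i]: 1.0 for i in prods})
        rid = f"R{j + 1}"
        constrained = rng.random() < spec.fraction_constrained or (
            spec.target == "infeasible" and j == 0
        )
        s_dot_x = sum(c * witness[names.index(n)] for n, c in stoich.items())
        if constrained:
            margin = rng.uniform(*_FORWARD_MARGIN)
            # forward-only, satisfied at the witness with `margin` to spare
            dg0[rid] = -rt * s_dot_x - margin
            direction = Directionality.FORWARD_ONLY
        else:
            dg0[rid] = float(rng.uniform(*spec.dg0_range))
            direction = Directionality.REVERSIBLE
        reactions.append(Reaction(id=rid, stoichiometry=stoich, directionality=direction))

    bounds = {name: (lo, hi) for name in names}

    if spec.target == "infeasible":
        # plant an impossible forward step over two fresh metabolites of
        # the existing pool: even substrate at c_max / product at c_min
        # leaves dG' positive by _INFEASIBLE_MARGIN
        s_name, p_name = names[0], names[1 % spec.n_metabolites]
        best_pull = rt * (log_lo - log_hi)  # most negative achievable RT*S.x
        rid = "R_blocked"
        dg0[rid] = _INFEASIBLE_MARGIN - best_pull
        reactions.append(
            Reaction(
                id=rid,
                stoichiometry={s_name: -1.0, p_name: 1.0},
                directionality=Directionality.FORWARD_ONLY,
            )
        )

    return ToyNetwork(
        reactions=tuple(reactions),
        dg0=dg0,
        bounds=bounds,
        conditions=conditions,
        expected_status=spec.target,
        witness_log_concentrations=dict(zip(names, witness.tolist())),
    )
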