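"""Network-embedded thermodynamic (NET) analysis.

Given a reaction network with standard transformed reaction energies,
measured metabolite concentration bounds and a set of fixed reaction
directions, NET analysis answers, by linear programming in
log-concentration space:

* is the dataset thermodynamically consistent at all (feasibility)?
* what range of dG' can each reaction attain (min/max of an affine
  objective over the feasible set)?
* how far do the thermodynamic constraints tighten each metabolite's
  concentration range?
* which initially-reversible reactions are forced into one direction
  (directionality assignment, iterated to a fixed point)?
* which reactions are displaced far from equilibrium (candidate
  regulatory sites, default threshold dG'_max < -10 kJ/mol)?

With x_i = ln(c_i), every reaction energy is affine,

    dG'_j(x) = dG'0_j + R*T * sum_i S_ij x_i,

concentration bounds become box bounds ln(c_min) <= x <= ln(c_max),
fixed directions become dG'_j <= -eps (forward) or >= +eps (backward)
-- LPs cannot express strict inequalities, so an epsilon margin
(default 1e-6 kJ/mol) stands in for them -- and cofactor-ratio bounds
become bounds on x_a - x_b.  Water never appears as a concentration
variable (activity 1); protons never appear at all.
"""

from __future__ import annotations

import math
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import linprog

from .constants import GAS_CONSTANT, WATER_NAMES
from .core import Conditions, Directionality, Reaction

__all__ = [
    "ConcentrationBounds",
    "RatioBound",
    "NetProblem",
    "GibbsRange",
    "FeasibilityResult",
    "SolverError",
    "build_problem",
    "check_feasibility",
    "dg_range",
    "concentration_range",
    "assign_directionality",
    "flag_regulatory_sites",
    "DEFAULT_CONCENTRATION_BOUNDS",
    "REGULATORY_THRESHOLD",
]

#: Physiological default bounds [mol/L] for unmeasured metabolites.
DEFAULT_CONCENTRATION_BOUNDS: tuple[float, float] = (1e-6, 5e-2)

#: dG'_max below this (strictly) flags a putative regulatory site, kJ/mol.
REGULATORY_THRESHOLD: float = -10.0


class SolverError(RuntimeError):
    """The LP backend failed numerically (distinct from infeasibility)."""


@dataclass(frozen=True)
class ConcentrationBounds:
    """Bounds [mol/L] for one reactant, tagged measured or default."""

    c_min: float
    c_max: float
    provenance: str = "default"

    def __post_init__(self) -> None:
        if not (0 < self.c_min <= self.c_max):
            raise ValueError(f"need 0 < c_min <= c_max, got [{self.c_min}, {self.c_max}]")


@dataclass(frozen=True)
class RatioBound:
    """lower <= c_numerator / c_denominator <= upper."""

    numerator: str
    denominator: str
    lower: float
    upper: float

    def __post_init__(self) -> None:
        if not (0 < self.lower <= self.upper):
            raise ValueError(f"need 0 < lower <= upper, got [{self.lower}, {self.upper}]")


@dataclass(frozen=True)
class GibbsRange:
    reaction_id: str
    dg_min: float
    dg_max: float
    status: str  # feasible | infeasible | unbounded

    def __post_init__(self) -> None:
        if self.status == "feasible" and self.dg_min > self.dg_max + 1e-9:
            raise ValueError(f"{self.reaction_id}: dg_min > dg_max")


@dataclass(frozen=True)
class FeasibilityResult:
    status: str  # feasible | infeasible
    certificate: tuple[str, ...] = ()

    @property
    def feasible(self) -> bool:
        return self.status == "feasible"


@dataclass(frozen=True)
class NetProblem:
    """An assembled NET LP: reactions, energies, bounds and constraints."""

    reactions: tuple[Reaction, ...]
    dg0: Mapping[str, float]
    conditions: Conditions
    bounds: Mapping[str, ConcentrationBounds]
    epsilon: float = 1e-6
    ratio_bounds: tuple[RatioBound, ...] = ()
    dg0_uncertainty: Mapping[str, float] = field(default_factory=dict)

    # derived, filled by build_problem
    variables: tuple[str, ...] = ()

    @property
    def rt(self) -> float:
        return GAS_CONSTANT * self.conditions.temperature

    def reaction(self, reaction_id: str) -> Reaction:
        for r in self.reactions:
            if r.id == reaction_id:
                return r
        raise KeyError(f"no reaction {reaction_id!r} in problem")

    def stoichiometry_row(self, reaction: Reaction) -> np.ndarray:
        """Coefficients of the concentration-bearing reactants of one reaction."""
        row = np.zeros(len(self.variables))
        index = {name: i for i, name in enumerate(self.variables)}
        for name, coeff in reaction.stoichiometry.items():
            if name in WATER_NAMES:
                continue
            row[index[name]] += coeff
        return row

    def with_directions(self, directions: Mapping[str, Directionality]) -> "NetProblem":
        """A copy with some reactions' directionality replaced."""
        reactions = tuple(
            replace(r, directionality=directions.get(r.id, r.directionality))
            for r in self.reactions
        )
        return replace(self, reactions=reactions)


def build_problem(
    reactions: Sequence[Reaction],
    dg0: Mapping[str, float],
    conditions: Conditions,
    bounds: Mapping[str, tuple[float, float] | ConcentrationBounds] | None = None,
    *,
    default_bounds: tuple[float, float] = DEFAULT_CONCENTRATION_BOUNDS,
    epsilon: float = 1e-6,
    ratio_bounds: Sequence[RatioBound] = (),
    dg0_uncertainty: Mapping[str, float] | None = None,
) -> NetProblem:
    """Assemble a :class:`NetProblem` from a model and measured bounds.

    Reactants without measured bounds get ``default_bounds`` tagged
    "default".  ``dg0_uncertainty`` optionally relaxes each reaction's
    standard energy to an interval dG'0 +/- err (off unless given).
    """
    reactions = tuple(reactions)
    if not reactions:
        raise ValueError("need at least one reaction")
    missing = [r.id for r in reactions if r.id not in dg0]
    if missing:
        raise KeyError(f"no dG'0 for reactions: {', '.join(missing)}")

    variables: list[str] = []
    for r in reactions:
        for name in r.stoichiometry:
            if name not in WATER_NAMES and name not in variables:
                variables.append(name)

    resolved: dict[str, ConcentrationBounds] = {}
    bounds = dict(bounds or {})
    for name in variables:
        raw = bounds.get(name)
        if raw is None:
            resolved[name] = ConcentrationBounds(*default_bounds, provenance="default")
        elif isinstance(raw, ConcentrationBounds):
            resolved[name] = raw
        else:
            resolved[name] = ConcentrationBounds(raw[0], raw[1], provenance="measured")
    # bounds for reactants absent from the network are tolerated but inert
    for rb in ratio_bounds:
        for name in (rb.numerator, rb.denominator):
            if name not in variables:
                raise KeyError(f"ratio bound references unknown reactant {name!r}")

    return NetProblem(
        reactions=reactions,
        dg0=dict(dg0),
        conditions=conditions,
        bounds=resolved,
        epsilon=epsilon,
        ratio_bounds=tuple(ratio_bounds),
        dg0_uncertainty=dict(dg0_uncertainty or {}),
        variables=tuple(variables),
    )


def _assemble(
    problem: NetProblem,
    directions: Mapping[str, Directionality] | None = None,
    drop_sign_for: str | None = None,
):
    """LP matrices: (A_ub, b_ub, var_bounds, row_names, n_extra).

    Variables are [x_1..x_m] plus, when dG'0 uncertainties are present,
    one bounded slack u_j per uncertain reaction (dG'0_j replaced by
    dG'0_j + u_j, |u_j| <= err_j).
    """
    rt = problem.rt
    m = len(problem.variables)
    uncertain = [r.id for r in problem.reactions if problem.dg0_uncertainty.get(r.id, 0.0) > 0]
    u_index = {rid: m + k for k, rid in enumerate(uncertain)}
    n = m + len(uncertain)

    rows: list[np.ndarray] = []
    rhs: list[float] = []
    names: list[str] = []
    for r in problem.reactions:
        direction = (directions or {}).get(r.id, r.directionality)
        if r.id == drop_sign_for or direction is Directionality.REVERSIBLE:
            continue
        coeff = np.zeros(n)
        coeff[:m] = rt * problem.stoichiometry_row(r)
        if r.id in u_index:
            coeff[u_index[r.id]] = 1.0
        if direction is Directionality.FORWARD_ONLY:
            rows.append(coeff)
            rhs.append(-problem.epsilon - problem.dg0[r.id])
            names.append(f"{r.id}: forward (dG' <= -eps)")
        else:
            rows.append(-coeff)
            rhs.append(problem.dg0[r.id] - problem.epsilon)
            names.append(f"{r.id}: backward (dG' >= +eps)")

    index = {name: i for i, name in enumerate(problem.variables)}
    for rb in problem.ratio_bounds:
        coeff = np.zeros(n)
        coeff[index[rb.numerator]] = 1.0
        coeff[index[rb.denominator]] = -1.0
        rows.append(coeff)
        rhs.append(math.log(rb.upper))
        names.append(f"ratio {rb.numerator}/{rb.denominator} <= {rb.upper:g}")
        rows.append(-coeff)
        rhs.append(-math.log(rb.lower))
        names.append(f"ratio {rb.numerator}/{rb.denominator} >= {rb.lower:g}")

    var_bounds = [
        (math.log(problem.bounds[name].c_min), math.log(problem.bounds[name].c_max))
        for name in problem.variables
    ]
    for rid in uncertain:
        err = problem.dg0_uncertainty[rid]
        var_bounds.append((-err, err))

    A = np.array(rows) if rows else np.empty((0, n))
    b = np.array(rhs)
    return A, b, var_bounds, names, len(uncertain)


def _solve(c, A, b, var_bounds):
    res = linprog(c, A_ub=A if len(A) else None, b_ub=b if len(A) else None,
                  bounds=var_bounds, method="highs")
    if res.status in (0, 2):
        return res
    raise SolverError(f"LP backend failure (status {res.status}): {res.message}")


def _constant_certificate(problem: NetProblem,
                          directions: Mapping[str, Directionality] | None = None) -> str | None:
    """A sign-constrained reaction with no concentration variables whose
    constant dG'0 violates its constraint is infeasible outright."""
    for r in problem.reactions:
        direction = (directions or {}).get(r.id, r.directionality)
        if direction is Directionality.REVERSIBLE:
            continue
        if np.any(problem.stoichiometry_row(r)) or problem.dg0_uncertainty.get(r.id, 0):
            continue
        dg = problem.dg0[r.id]
        if direction is Directionality.FORWARD_ONLY and dg > -problem.epsilon:
            return f"{r.id}: constant dG'0 = {dg:g} violates forward constraint"
        if direction is Directionality.BACKWARD_ONLY and dg < problem.epsilon:
            return f"{r.id}: constant dG'0 = {dg:g} violates backward constraint"
    return None


def check_feasibility(problem: NetProblem,
                      directions: Mapping[str, Directionality] | None = None) -> FeasibilityResult:
    """Is there any concentration assignment satisfying every constraint?

    On infeasibility the certificate is an irreducible subset of the
    sign/ratio constraints (found by deletion filtering) that is already
    infeasible on its own under the box bounds.
    """
    const = _constant_certificate(problem, directions)
    if const is not None:
        return FeasibilityResult(status="infeasible", certificate=(const,))
    A, b, var_bounds, names, _ = _assemble(problem, directions)
    c = np.zeros(A.shape[1] if A.size else len(var_bounds))
    res = _solve(c, A, b, var_bounds)
    if res.status == 0:
        return FeasibilityResult(status="feasible")
    keep = list(range(len(names)))
    for i in list(keep):
        trial = [j for j in keep if j != i]
        res_t = _solve(c, A[trial], b[trial], var_bounds)
        if res_t.status == 2:
            keep = trial
    return FeasibilityResult(status="infeasible", certificate=tuple(names[i] for i in keep))


def dg_range(problem: NetProblem, reaction_id: str, *,
             keep_own_sign: bool = True,
             directions: Mapping[str, Directionality] | None = None) -> GibbsRange:
    """Feasible [dG'_min, dG'_max] of one reaction (two LP solves).

    The reaction's own sign constraint stays active while ranging unless
    ``keep_own_sign=False``: the range describes the feasible set as
    constrained, not a hypothetical relaxation.
    """
    reaction = problem.reaction(reaction_id)
    A, b, var_bounds, _, n_extra = _assemble(
        problem, directions, drop_sign_for=None if keep_own_sign else reaction_id
    )
    n = len(var_bounds)
    obj = np.zeros(n)
    obj[: len(problem.variables)] = problem.rt * problem.stoichiometry_row(reaction)
    if problem.dg0_uncertainty.get(reaction_id, 0.0) > 0:
        uncertain = [r.id for r in problem.reactions
                     if problem.dg0_uncertainty.get(r.id, 0.0) > 0]
        obj[len(problem.variables) + uncertain.index(reaction_id)] = 1.0

    if _constant_certificate(problem, directions) is not None:
        return GibbsRange(reaction_id, math.nan, math.nan, status="infeasible")
    lo = _solve(obj, A, b, var_bounds)
    if lo.status == 2:
        return GibbsRange(reaction_id, math.nan, math.nan, status="infeasible")
    hi = _solve(-obj, A, b, var_bounds)
    base = problem.dg0[reaction_id]
    return GibbsRange(reaction_id, base + lo.fun, base - hi.fun, status="feasible")


def concentration_range(problem: NetProblem, reactant_id: str, *,
                        directions: Mapping[str, Directionality] | None = None
                        ) -> tuple[float, float]:
    """Thermodynamically tightened [c_min, c_max] of one reactant [mol/L].

    Always within the input bounds (the LP can only remove volume from
    the box, never add it); equals them when no sign or ratio constraint
    touches the reactant.
    """
    if reactant_id not in problem.variables:
        raise KeyError(f"no concentration variable for {reactant_id!r}")
    i = problem.variables.index(reactant_id)
    A, b, var_bounds, _, _ = _assemble(problem, directions)
    obj = np.zeros(len(var_bounds))
    obj[i] = 1.0
    lo = _solve(obj, A, b, var_bounds)
    hi = _solve(-obj, A, b, var_bounds)
    if lo.status == 2 or hi.status == 2:
        raise ValueError("problem is infeasible; no concentration range exists")
    given = problem.bounds[reactant_id]
    c_lo = min(max(math.exp(lo.fun), given.c_min), given.c_max)
    c_hi = max(min(math.exp(-hi.fun), given.c_max), given.c_min)
    return (c_lo, c_hi)


def assign_directionality(problem: NetProblem) -> dict[str, Directionality]:
    """Force directions onto initially-reversible reactions where the
    feasible dG' range has a definite sign; iterate to a fixed point.

    A reaction becomes forward-only when its dG'_max < -eps (every
    feasible state drives it forward) and backward-only when
    dG'_min > +eps.  Each new assignment is added as a constraint and
    the sweep repeats, since constraints can propagate through shared
    metabolites; a fixed point must arrive within |reactions| sweeps.
    """
    directions = {r.id: r.directionality for r in problem.reactions}
    if not check_feasibility(problem).feasible:
        raise ValueError("cannot assign directionality: problem is infeasible")
    for _ in range(len(problem.reactions) + 1):
        changed = False
        for r in problem.reactions:
            if directions[r.id] is not Directionality.REVERSIBLE:
                continue
            rng = dg_range(problem, r.id, directions=directions)
            if rng.status != "feasible":  # pragma: no cover - guarded by check above
                raise ValueError("problem became infeasible during assignment")
            if rng.dg_max < -problem.epsilon:
                directions[r.id] = Directionality.FORWARD_ONLY
                changed = True
            elif rng.dg_min > problem.epsilon:
                directions[r.id] = Directionality.BACKWARD_ONLY
                changed = True
        if not changed:
            return directions
    raise RuntimeError(
        "directionality assignment did not reach a fixed point within "
        f"{len(problem.reactions)} sweeps"
    )


def flag_regulatory_sites(problem: NetProblem, *,
                          threshold: float = REGULATORY_THRESHOLD,
                          ranges: Mapping[str, GibbsRange] | None = None) -> set[str]:
    """Reactions displaced from equilibrium: dG'_max strictly below threshold."""
    if ranges is None:
        ranges = {r.id: dg_range(problem, r.id) for r in problem.reactions}
    return {
        rid for rid, rng in ranges.items()
        if rng.status == "feasible" and rng.dg_max < threshold
    }
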