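"""Flow-force relation for a reversible unimolecular enzymatic reaction.

Far-from-equilibrium kinetics of S <-> P under mass conservation
(C_s + C_p = C constant) collapse, at steady state, to a one-variable
relation between the normalized net rate and the affinity A = -dG_r:

    v / v_s_max = (exp(A/RT) - 1)
                  / ((K_s/C + 1) * exp(A/RT) + (v_s_max/v_p_max) * (K_p/C + 1))

The rate is zero at A = 0, strictly increasing in A, and saturates at
1/(K_s/C + 1) as A grows.  Near equilibrium the relation is
proportional, v = L*A, with phenomenological coefficient L (the enzyme
capacity); for a thermodynamically irreversible parameterization the
proportional regime collapses and the curve becomes linear-with-offset
at larger A.  :data:`FIG3_REVERSIBLE` and :data:`FIG3_IRREVERSIBLE`
bundle the two contrasting parameter sets used for that comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .constants import DEFAULT_TEMPERATURE, GAS_CONSTANT

__all__ = [
    "FlowForceParams",
    "SweepResult",
    "rate_at_affinity",
    "sweep",
    "phenomenological_coefficient",
    "FIG3_REVERSIBLE",
    "FIG3_IRREVERSIBLE",
]


@dataclass(frozen=True)
class FlowForceParams:
    """Kinetic and conservation parameters of the unimolecular reaction.

    Rates may be in any unit (only the ratio vs_max/vp_max enters the
    normalized rate); K's and the conserved total C are mol/L.
    """

    vs_max: float
    vp_max: float
    ks: float
    kp: float
    c_total: float
    temperature: float = DEFAULT_TEMPERATURE

    def __post_init__(self) -> None:
        for name in ("vs_max", "vp_max", "ks", "kp", "c_total", "temperature"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")

    @property
    def rt(self) -> float:
        return GAS_CONSTANT * self.temperature


#: Thermodynamically reversible parameter set (equal capacities,
#: K_p = K_s = 1 mM, C = 10 mM): near-proportional flow-force curve.
FIG3_REVERSIBLE = FlowForceParams(vs_max=100.0, vp_max=100.0, ks=1e-3, kp=1e-3, c_total=1e-2)

#: Thermodynamically irreversible set (weak backward capacity,
#: K_p = 10 mM): linear-with-offset behavior at larger affinity.
FIG3_IRREVERSIBLE = FlowForceParams(vs_max=100.0, vp_max=1.0, ks=1e-3, kp=1e-2, c_total=1e-2)


def rate_at_affinity(affinity, params: FlowForceParams):
    """Normalized net rate v/vs_max at affinity A [kJ/mol].

    Accepts scalars or arrays; the evaluation is overflow-safe for
    arbitrarily large |A| (both exponential forms of the expression are
    used on their stable half-lines).
    """
    a_coef = params.ks / params.c_total + 1.0
    b_coef = (params.vs_max / params.vp_max) * (params.kp / params.c_total + 1.0)
    x = np.asarray(affinity, dtype=float) / params.rt

    pos = x >= 0
    out = np.empty_like(x)
    # x >= 0: divide through by exp(x) -> (1 - e^-x) / (a + b e^-x)
    with np.errstate(over="ignore"):
        exp_neg = np.exp(-np.where(pos, x, 0.0))
        out[pos] = (-np.expm1(-x[pos])) / (a_coef + b_coef * exp_neg[pos])
        # x < 0: e^x is safe directly
        exp_pos = np.exp(np.where(pos, 0.0, x))
        out[~pos] = np.expm1(x[~pos]) / (a_coef * exp_pos[~pos] + b_coef)
    if np.isscalar(affinity) or np.ndim(affinity) == 0:
        return float(out)
    return out


def saturation_limit(params: FlowForceParams) -> float:
    """Algebraic A -> infinity limit of v/vs_max: 1/(K_s/C + 1)."""
    return 1.0 / (params.ks / params.c_total + 1.0)


@dataclass(frozen=True)
class SweepResult:
    """Affinity sweep: the (A, v) curve and the near-equilibrium slope L."""

    table: pd.DataFrame  # columns: affinity_kj_mol, rate_normalized
    slope: float  # L of v = L*A, per kJ/mol


def sweep(params: FlowForceParams, affinities) -> SweepResult:
    """Evaluate the curve on a grid covering A = 0 and fit v = L*A.

    L is the least-squares slope through the origin over the
    near-equilibrium window |A| < RT; it converges to the analytic
    origin slope 1/(RT*(a+b)) as the grid refines around zero.
    """
    a_grid = np.asarray(affinities, dtype=float)
    if not (a_grid.min() <= 0.0 <= a_grid.max()):
        raise ValueError("affinity grid must cover A = 0")
    v = rate_at_affinity(a_grid, params)
    window = np.abs(a_grid) < params.rt
    if not window.any():
        raise ValueError("no grid points in the near-equilibrium window |A| < RT")
    aw, vw = a_grid[window], v[window]
    denom = float(np.dot(aw, aw))
    slope = float(np.dot(aw, vw) / denom) if denom > 0 else _origin_slope(params)
    table = pd.DataFrame({"affinity_kj_mol": a_grid, "rate_normalized": v})
    return SweepResult(table=table, slope=slope)


def phenomenological_coefficient(params: FlowForceParams) -> float:
    """Analytic L of the near-equilibrium law v = L*A: dv/dA at A = 0.

    Equals 1/(RT*(K_s/C + 1 + (vs_max/vp_max)*(K_p/C + 1))), per kJ/mol
    of affinity (normalized rate units).
    """
    a_coef = params.ks / params.c_total + 1.0
    b_coef = (params.vs_max / params.vp_max) * (params.kp / params.c_total + 1.0)
    return 1.0 / (params.rt * (a_coef + b_coef))


_origin_slope = phenomenological_coefficient
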