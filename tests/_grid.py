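"""Dense log-grid enumeration oracle for small NET problems.

Independent of the LP path: the feasible set is sampled on a dense grid
in log-concentration space and reaction-energy extremes are read off
the admissible points.  Because a grid can both miss thin feasible
slivers and miss the continuous optimum between nodes, every quantity
is computed twice:

* "strict" admissibility applies the sign constraints exactly; strict
  grid points are genuinely feasible, so strict extremes bound the LP
  optimum from inside.
* "relaxed" admissibility loosens each sign constraint by its
  half-grid-step Lipschitz slack; any continuous feasible point rounds
  to a relaxed-admissible grid node, so relaxed extremes (plus the same
  objective slack) bound the LP optimum from outside.

Together: strict_max <= lp_max <= relaxed_max + step for each reaction.
"""

from __future__ import annotations

import itertools

import numpy as np

from thermonet.core import Directionality
from thermonet.net import NetProblem


def _grid_setup(problem: NetProblem, n_points: int):
    rt = problem.rt
    axes, steps = [], []
    for name in problem.variables:
        b = problem.bounds[name]
        axis = np.linspace(np.log(b.c_min), np.log(b.c_max), n_points)
        axes.append(axis)
        steps.append(axis[1] - axis[0] if n_points > 1 else 0.0)
    mesh = np.meshgrid(*axes, indexing="ij")
    points = np.stack([m.ravel() for m in mesh], axis=1)  # (N, m)
    stoich = np.stack([problem.stoichiometry_row(r) for r in problem.reactions])  # (r, m)
    dg0 = np.array([problem.dg0[r.id] for r in problem.reactions])
    dg = dg0[None, :] + rt * points @ stoich.T  # (N, r)
    # half-step Lipschitz slack of each reaction's energy under rounding
    slack = 0.5 * rt * np.abs(stoich) @ np.asarray(steps)
    return dg, slack


def _sign_masks(problem: NetProblem, dg: np.ndarray, slack: np.ndarray,
                directions=None):
    strict = np.ones(dg.shape[0], dtype=bool)
    relaxed = np.ones(dg.shape[0], dtype=bool)
    eps = problem.epsilon
    for j, r in enumerate(problem.reactions):
        direction = (directions or {}).get(r.id, r.directionality)
        if direction is Directionality.FORWARD_ONLY:
            strict &= dg[:, j] <= -eps
            relaxed &= dg[:, j] <= -eps + slack[j]
        elif direction is Directionality.BACKWARD_ONLY:
            strict &= dg[:, j] >= eps
            relaxed &= dg[:, j] >= eps - slack[j]
    return strict, relaxed


def grid_dg_extremes(problem: NetProblem, n_points: int = 21):
    """Per-reaction (strict_min, strict_max, relaxed_min, relaxed_max, step).

    Strict entries are None when no strictly admissible grid point
    exists; ``step`` is the objective-rounding slack of that reaction.
    """
    dg, slack = _grid_setup(problem, n_points)
    strict, relaxed = _sign_masks(problem, dg, slack)
    out = {}
    for j, r in enumerate(problem.reactions):
        col = dg[:, j]
        s_lo = float(col[strict].min()) if strict.any() else None
        s_hi = float(col[strict].max()) if strict.any() else None
        r_lo = float(col[relaxed].min()) if relaxed.any() else None
        r_hi = float(col[relaxed].max()) if relaxed.any() else None
        out[r.id] = (s_lo, s_hi, r_lo, r_hi, float(slack[j]))
    return out


def grid_feasible(problem: NetProblem, n_points: int = 21):
    """(strict_feasible, relaxed_feasible) of the whole constraint set."""
    dg, slack = _grid_setup(problem, n_points)
    strict, relaxed = _sign_masks(problem, dg, slack)
    return bool(strict.any()), bool(relaxed.any())


def enumerate_direction_patterns(problem: NetProblem, n_points: int = 21):
    """Oracle directionality by exhaustive sign-pattern enumeration.

    Every forward/backward pattern over the initially-reversible
    reactions is checked for grid feasibility; a reaction is
    forward-only when no feasible pattern runs it backward, and vice
    versa.  Patterns whose strict and relaxed verdicts disagree make
    the instance indeterminate at this grid resolution (returns None).
    """
    dg, slack = _grid_setup(problem, n_points)
    reversible = [r.id for r in problem.reactions
                  if r.directionality is Directionality.REVERSIBLE]
    feasible_patterns = []
    for pattern in itertools.product(
        (Directionality.FORWARD_ONLY, Directionality.BACKWARD_ONLY), repeat=len(reversible)
    ):
        directions = dict(zip(reversible, pattern))
        strict, relaxed = _sign_masks(problem, dg, slack, directions)
        if strict.any():
            feasible_patterns.append(pattern)
        elif relaxed.any():
            return None  # boundary case: grid cannot decide this pattern
    verdict = {}
    for k, rid in enumerate(reversible):
        runs_forward = any(p[k] is Directionality.FORWARD_ONLY for p in feasible_patterns)
        runs_backward = any(p[k] is Directionality.BACKWARD_ONLY for p in feasible_patterns)
        if runs_forward and runs_backward:
            verdict[rid] = Directionality.REVERSIBLE
        elif runs_forward:
            verdict[rid] = Directionality.FORWARD_ONLY
        elif runs_backward:
            verdict[rid] = Directionality.BACKWARD_ONLY
        else:
            return None  # neither direction strictly attainable on the grid
    return verdict
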