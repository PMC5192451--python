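"""NET analysis: LP assembly, feasibility, ranges, directionality."""

import math

import numpy as np
import pytest

from _grid import grid_dg_extremes
from thermonet.constants import GAS_CONSTANT
from thermonet.core import Conditions, Directionality, Reaction
from thermonet.net import (
    ConcentrationBounds,
    RatioBound,
    assign_directionality,
    build_problem,
    check_feasibility,
    concentration_range,
    dg_range,
    flag_regulatory_sites,
)
from thermonet.toynet import ToyNetworkSpec, generate_toy_network

COND = Conditions()
RT = GAS_CONSTANT * 298.15
WIDE = (1e-6, 1e-1)


def _rxn(rid, stoich, direction=Directionality.REVERSIBLE):
    return Reaction(id=rid, stoichiometry=stoich, directionality=direction)


class TestBuildProblem:
    def test_glycolysis_has_sixteen_concentration_variables(
        self, glycolysis_reactions, glycolysis_dg0
    ):
        # 17 reactants in the fixture; water carries no concentration variable
        problem = build_problem(glycolysis_reactions, glycolysis_dg0, COND)
        assert len(problem.variables) == 16
        assert "H2O" not in problem.variables

    def test_single_reversible_reaction_trivially_feasible(self):
        problem = build_problem([_rxn("r", {"A": -1.0, "B": 1.0})], {"r": 5.0}, COND)
        assert check_feasibility(problem).feasible

    def test_default_bounds_tagged(self):
        problem = build_problem(
            [_rxn("r", {"A": -1.0, "B": 1.0})], {"r": 0.0}, COND,
            bounds={"A": (1e-4, 1e-2)},
        )
        assert problem.bounds["A"].provenance == "measured"
        assert problem.bounds["B"].provenance == "default"

    def test_missing_dg0_rejected(self):
        with pytest.raises(KeyError, match="r2"):
            build_problem([_rxn("r2", {"A": -1.0, "B": 1.0})], {}, COND)

    def test_constant_reaction_violating_its_sign_is_certified(self):
        # only water on both sides: no concentration freedom at all
        rxn = _rxn("wsplit", {"H2O": -1.0, "h2o": 1.0}, Directionality.BACKWARD_ONLY)
        problem = build_problem([rxn], {"wsplit": -3.0}, COND)
        result = check_feasibility(problem)
        assert not result.feasible
        assert "wsplit" in result.certificate[0]


class TestFeasibility:
    def test_forward_chain_with_negative_energies(self):
        reactions = [
            _rxn("r1", {"A": -1.0, "B": 1.0}, Directionality.FORWARD_ONLY),
            _rxn("r2", {"B": -1.0, "C": 1.0}, Directionality.FORWARD_ONLY),
        ]
        problem = build_problem(reactions, {"r1": -10.0, "r2": -10.0}, COND)
        assert check_feasibility(problem).feasible

    def test_overconstrained_forward_step_infeasible(self):
        # S -> P with dG'0 = +50: even S at c_max, P at c_min leaves
        # dG' = 50 + RT*ln(1e-5) = +21.5 > 0
        rxn = _rxn("blocked", {"S": -1.0, "P": 1.0}, Directionality.FORWARD_ONLY)
        problem = build_problem(
            [rxn], {"blocked": 50.0}, COND, {"S": WIDE, "P": WIDE}
        )
        result = check_feasibility(problem)
        assert result.status == "infeasible"
        assert any("blocked" in line for line in result.certificate)

    def test_infeasibility_certificate_is_irreducible(self):
        reactions = [
            _rxn("ok", {"A": -1.0, "B": 1.0}, Directionality.FORWARD_ONLY),
            _rxn("blocked", {"S": -1.0, "P": 1.0}, Directionality.FORWARD_ONLY),
        ]
        problem = build_problem(
            reactions, {"ok": -5.0, "blocked": 50.0}, COND,
            {"S": WIDE, "P": WIDE},
        )
        result = check_feasibility(problem)
        assert len(result.certificate) == 1
        assert "blocked" in result.certificate[0]

    def test_no_sign_constraints_always_feasible(self, glycolysis_reactions, glycolysis_dg0):
        problem = build_problem(glycolysis_reactions, glycolysis_dg0, COND)
        assert check_feasibility(problem).feasible

    def test_determinism(self):
        net = generate_toy_network(ToyNetworkSpec(seed=11, n_reactions=4))
        results = []
        for _ in range(3):
            problem = build_problem(net.reactions, net.dg0, net.conditions, net.bounds)
            ranges = tuple(
                (r.id, dg_range(problem, r.id).dg_min, dg_range(problem, r.id).dg_max)
                for r in problem.reactions
            )
            results.append((check_feasibility(problem).status, ranges))
        assert results[0] == results[1] == results[2]


class TestDgRange:
    def test_fixed_concentrations_collapse_the_range(self):
        rxn = _rxn("r", {"S": -1.0, "P": 1.0})
        problem = build_problem(
            [rxn], {"r": -3.0}, COND,
            {"S": ConcentrationBounds(1e-3, 1e-3, "measured"),
             "P": ConcentrationBounds(1e-4, 1e-4, "measured")},
        )
        rng = dg_range(problem, "r")
        expected = -3.0 + RT * math.log(1e-4 / 1e-3)
        assert rng.dg_min == pytest.approx(expected, abs=1e-6)
        assert rng.dg_max == pytest.approx(expected, abs=1e-6)

    def test_standard_value_inside_range_with_1m_in_bounds(self):
        rxn = _rxn("r", {"S": -1.0, "P": 1.0})
        problem = build_problem([rxn], {"r": 4.2}, COND, {"S": (0.1, 10.0), "P": (0.1, 10.0)})
        rng = dg_range(problem, "r")
        assert rng.dg_min <= 4.2 <= rng.dg_max

    def test_matches_grid_enumeration(self):
        net = generate_toy_network(ToyNetworkSpec(seed=5, n_metabolites=3, n_reactions=3))
        problem = build_problem(net.reactions, net.dg0, net.conditions, net.bounds)
        oracle = grid_dg_extremes(problem, n_points=31)
        for r in problem.reactions:
            rng = dg_range(problem, r.id)
            s_lo, s_hi, r_lo, r_hi, step = oracle[r.id]
            assert rng.dg_max >= s_hi - 1e-7
            assert rng.dg_max <= r_hi + step + 1e-7
            assert rng.dg_min <= s_lo + 1e-7
            assert rng.dg_min >= r_lo - step - 1e-7

    def test_own_sign_constraint_kept_while_ranging(self):
        rxn = _rxn("r", {"S": -1.0, "P": 1.0}, Directionality.FORWARD_ONLY)
        problem = build_problem([rxn], {"r": 0.0}, COND, {"S": WIDE, "P": WIDE})
        kept = dg_range(problem, "r")
        assert kept.dg_max <= 0.0
        dropped = dg_range(problem, "r", keep_own_sign=False)
        assert dropped.dg_max > 0.0

    def test_adding_constraints_never_widens_ranges(self, glycolysis_reactions,
                                                    glycolysis_dg0):
        base = build_problem(glycolysis_reactions, glycolysis_dg0, COND)
        constrained = build_problem(
            glycolysis_reactions, glycolysis_dg0, COND,
            bounds={"ATP": (1e-3, 1e-2), "ADP": (1e-4, 1e-3)},
            ratio_bounds=[RatioBound("NADH", "NAD", 0.01, 1.0)],
        )
        for r in base.reactions:
            wide = dg_range(base, r.id)
            tight = dg_range(constrained, r.id)
            assert tight.dg_min >= wide.dg_min - 1e-7
            assert tight.dg_max <= wide.dg_max + 1e-7


class TestConcentrationRange:
    def test_unconstrained_returns_input_bounds(self):
        problem = build_problem(
            [_rxn("r", {"A": -1.0, "B": 1.0})], {"r": 0.0}, COND,
            {"A": (1e-5, 1e-2), "B": (1e-5, 1e-2)},
        )
        assert concentration_range(problem, "A") == pytest.approx((1e-5, 1e-2))

    def test_forward_step_tightens_product_upper_bound(self):
        # S -> P, dG'0 = 0, S fixed at 1 mM: feasibility forces c_P < 1 mM
        rxn = _rxn("r", {"S": -1.0, "P": 1.0}, Directionality.FORWARD_ONLY)
        problem = build_problem(
            [rxn], {"r": 0.0}, COND,
            {"S": ConcentrationBounds(1e-3, 1e-3, "measured"), "P": (1e-6, 1e-1)},
        )
        lo, hi = concentration_range(problem, "P")
        assert hi < 1e-3 + 1e-12
        assert lo == pytest.approx(1e-6)

    def test_always_within_input_bounds(self):
        net = generate_toy_network(ToyNetworkSpec(seed=3, n_reactions=4))
        problem = build_problem(net.reactions, net.dg0, net.conditions, net.bounds)
        for name in problem.variables:
            lo, hi = concentration_range(problem, name)
            b = problem.bounds[name]
            assert b.c_min - 1e-15 <= lo <= hi <= b.c_max + 1e-15

    def test_infeasible_problem_raises(self):
        rxn = _rxn("blocked", {"S": -1.0, "P": 1.0}, Directionality.FORWARD_ONLY)
        problem = build_problem([rxn], {"blocked": 50.0}, COND, {"S": WIDE, "P": WIDE})
        with pytest.raises(ValueError, match="infeasible"):
            concentration_range(problem, "S")


class TestAssignDirectionality:
    def test_definitely_forward_reaction(self):
        # feasible dG' range entirely negative -> forward-only
        rxn = _rxn("r", {"S": -1.0, "P": 1.0})
        problem = build_problem(
            [rxn], {"r": -30.0}, COND, {"S": (1e-4, 1e-2), "P": (1e-4, 1e-2)}
        )
        assert assign_directionality(problem)["r"] is Directionality.FORWARD_ONLY

    def test_straddling_range_stays_reversible(self):
        rxn = _rxn("r", {"S": -1.0, "P": 1.0})
        problem = build_problem([rxn], {"r": 0.5}, COND, {"S": WIDE, "P": WIDE})
        assert assign_directionality(problem)["r"] is Directionality.REVERSIBLE

    def test_definitely_backward_reaction(self):
        rxn = _rxn("r", {"S": -1.0, "P": 1.0})
        problem = build_problem(
            [rxn], {"r": 30.0}, COND, {"S": (1e-4, 1e-2), "P": (1e-4, 1e-2)}
        )
        assert assign_directionality(problem)["r"] is Directionality.BACKWARD_ONLY

    def test_preassigned_directions_are_kept(self):
        reactions = [
            _rxn("fixed", {"A": -1.0, "B": 1.0}, Directionality.FORWARD_ONLY),
            _rxn("free", {"B": -1.0, "C": 1.0}),
        ]
        problem = build_problem(reactions, {"fixed": -5.0, "free": 0.0}, COND)
        assigned = assign_directionality(problem)
        assert assigned["fixed"] is Directionality.FORWARD_ONLY

    def test_assignment_remains_feasible(self):
        net = generate_toy_network(ToyNetworkSpec(seed=21, n_reactions=4,
                                                  fraction_constrained=0.3))
        problem = build_problem(net.reactions, net.dg0, net.conditions, net.bounds)
        assigned = assign_directionality(problem)
        assert check_feasibility(problem.with_directions(assigned)).feasible

    def test_infeasible_problem_rejected(self):
        rxn = _rxn("blocked", {"S": -1.0, "P": 1.0}, Directionality.FORWARD_ONLY)
        problem = build_problem([rxn], {"blocked": 50.0}, COND, {"S": WIDE, "P": WIDE})
        with pytest.raises(ValueError, match="infeasible"):
            assign_directionality(problem)


class TestRegulatorySites:
    def _single(self, dg0_value):
        rxn = _rxn("r", {"S": -1.0, "P": 1.0})
        return build_problem(
            [rxn], {"r": dg0_value}, COND,
            {"S": ConcentrationBounds(1e-3, 1e-3, "measured"),
             "P": ConcentrationBounds(1e-3, 1e-3, "measured")},
        )

    def test_far_from_equilibrium_flagged(self):
        assert flag_regulatory_sites(self._single(-12.0)) == {"r"}

    def test_near_equilibrium_not_flagged(self):
        assert flag_regulatory_sites(self._single(-5.0)) == set()

    def test_threshold_is_strict(self):
        assert flag_regulatory_sites(self._single(-10.0)) == set()

    def test_configurable_threshold(self):
        assert flag_regulatory_sites(self._single(-5.0), threshold=-4.0) == {"r"}


class TestGlycolysisNetwork:
    def test_feasible_under_physiological_bounds(self, glycolysis_reactions,
                                                 glycolysis_dg0, yeast_conditions):
        problem = build_problem(glycolysis_reactions, glycolysis_dg0, yeast_conditions)
        assert check_feasibility(problem).feasible

    def test_all_forward_pathway_is_feasible(self, glycolysis_reactions,
                                             glycolysis_dg0, yeast_conditions):
        # physiological concentrations can drive every glycolytic step forward
        forward = [
            Reaction(id=r.id, stoichiometry=r.stoichiometry,
                     directionality=Directionality.FORWARD_ONLY)
            for r in glycolysis_reactions
        ]
        problem = build_problem(forward, glycolysis_dg0, yeast_conditions)
        assert check_feasibility(problem).feasible


class TestDg0Uncertainty:
    def test_uncertainty_widens_ranges(self):
        rxn = _rxn("r", {"S": -1.0, "P": 1.0})
        tight = build_problem([rxn], {"r": 2.0}, COND, {"S": WIDE, "P": WIDE})
        relaxed = build_problem([rxn], {"r": 2.0}, COND, {"S": WIDE, "P": WIDE},
                                dg0_uncertainty={"r": 3.0})
        t, rel = dg_range(tight, "r"), dg_range(relaxed, "r")
        assert rel.dg_min == pytest.approx(t.dg_min - 3.0, abs=1e-6)
        assert rel.dg_max == pytest.approx(t.dg_max + 3.0, abs=1e-6)

    def test_uncertainty_can_rescue_feasibility(self):
        rxn = _rxn("r", {"S": -1.0, "P": 1.0}, Directionality.FORWARD_ONLY)
        dg0 = {"r": RT * math.log(1e5) + 1.0}  # just beyond the bounds' reach
        infeasible = build_problem([rxn], dg0, COND, {"S": WIDE, "P": WIDE})
        assert not check_feasibility(infeasible).feasible
        rescued = build_problem([rxn], dg0, COND, {"S": WIDE, "P": WIDE},
                                dg0_uncertainty={"r": 5.0})
        assert check_feasibility(rescued).feasible
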