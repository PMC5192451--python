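# thermonet

Thermodynamics-based analysis of metabolic networks, for systems
biologists who want to know whether a measured metabolome is consistent
with an assumed set of reaction directions — and what that consistency
implies about Gibbs energies, concentration ranges, reversibility and
likely regulatory sites.

## What it computes

**Transformed formation energies.** Intracellular conditions differ
from the biochemical standard state, so each species' standard Gibbs
energy of formation Δ<sub>f</sub>G⁰ is Legendre-transformed to the
compartment's pH and corrected for ionic strength *I* with the extended
Debye–Hückel equation:

    Δ_fG′⁰ = Δ_fG⁰ − N_H·RT·ln(10^−pH) − RT·ln10·A·(z² − N_H)·√I/(1 + B·√I)

with *A* = 0.510651, *B* = 1.6 (valid for *I* between 0.005 and
0.25 M). A biochemical reactant (ATP, Pi, …) is a pseudoisomer group of
protonation states at internal equilibrium; its reactant-level energy
is the log-sum-exp merge

    Δ_fG_j′⁰ = −RT·ln Σ_i exp(−Δ_fG_i′⁰/RT)

and reaction energies are stoichiometric sums Δ<sub>r</sub>G′⁰ =
Σ S<sub>ij</sub>·Δ<sub>f</sub>G<sub>i</sub>′⁰, with
Δ<sub>r</sub>G′ = Δ<sub>r</sub>G′⁰ + RT·Σ S<sub>ij</sub>·ln c<sub>i</sub>
at actual concentrations (water activity 1; protons absorbed into the
constant-pH transform).

**Group contribution.** Where no measured Δ<sub>f</sub>G⁰ exists, it is
estimated from a functional-group decomposition,
Δ<sub>f</sub>G⁰ = P₀ + Σ n<sub>j</sub>P<sub>j</sub>; two published
contribution sets are bundled with the classic ring-form glucose
decomposition.

**Transport reactions.** Cross-membrane steps add an electrical term
nFΔΨ and a pH-gradient term built from compartment-specific transformed
energies and −2.3RT·Σ s<sub>i</sub>N<sub>H</sub>(i)·pH<sub>i</sub>.

**NET analysis.** With x = ln c the reaction energies are affine, so
feasibility of a network + concentration bounds + fixed directions is a
linear program; further LPs give each reaction's attainable
[Δ<sub>r</sub>G′<sub>min</sub>, Δ<sub>r</sub>G′<sub>max</sub>], tighten
metabolite concentration ranges, assign directions to initially
reversible reactions (iterated to a fixed point) and flag reactions far
from equilibrium (Δ<sub>r</sub>G′<sub>max</sub> < −10 kJ/mol) as
putative regulatory sites.

**Flow-force relation.** For a single reversible unimolecular enzymatic
reaction under mass conservation, the net rate as a function of
affinity A = −Δ<sub>r</sub>G, including the near-equilibrium
proportional law v = L·A and its breakdown for thermodynamically
irreversible parameterizations.

## Worked example

A yeast-glycolysis fixture (species table and ten reaction equations)
is bundled; the CLI defaults to it:

```sh
$ thermonet transform | head -4
reactant        dfg0_prime_kj_mol
3-Phospho-glyceroyl phosphate   -2206.3523
2-Phospho-glycerate     -1341.5090
3-Phospho-glycerate     -1347.4070

$ thermonet dg0 | head -3
reactant        dg0_prime_kj_mol
HEX1    -24.5758
PGI     3.1974
```

At cytosolic pH 7 and *I* = 0.15 M, glucose's formation energy moves
from −915.9 to −428.06 kJ/mol, and the hexokinase reaction
(Glucose + ATP = Glucose 6-phosphate + ADP) has Δ<sub>r</sub>G′⁰ =
−24.58 kJ/mol: strongly forward, as expected for the committed first
step of the pathway. The same library calls are available in Python:

```python
from thermonet import fixtures, build_problem, check_feasibility, dg_range

problem = build_problem(
    fixtures.glycolysis_reactions(),
    fixtures.glycolysis_dg0(),
    fixtures.yeast_conditions(),
)
check_feasibility(problem).status   # 'feasible'
dg_range(problem, "HEX1")           # GibbsRange(dg_min=-78.2, dg_max=29.1, ...)
```

`thermonet net-check` exits 0/1 for feasible/infeasible (2 on malformed
input); `net-range`, `direction` and `regulatory` emit TSV reports;
`groupgc`, `flowforce` and `make-toy` cover the remaining components.

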