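# Methods

## Scope and model

The package treats a metabolic network as a set of reactions written
over *reactants* — pseudoisomer groups of protonation states assumed to
be at internal equilibrium — rather than over individual chemical
species. Three layers sit on top of each other:

1. **Species → reactant energetics.** Each species carries a standard
   Gibbs energy of formation Δ_fG⁰ (kJ/mol), a charge z and a hydrogen
   count N_H. At specified pH, ionic strength I (mol/L) and temperature
   T (K) the Legendre transform plus the extended Debye–Hückel
   correction give the species-level Δ_fG′⁰; a log-sum-exp merge over
   the group gives the reactant-level value. The merge is evaluated in
   shifted form (scipy's `logsumexp`), so groups whose species differ
   by hundreds of kJ/mol do not overflow; the result is always at or
   below the lowest species energy and approaches it as the gap grows.
2. **Reaction energetics.** Δ_rG′⁰ is the stoichiometric sum of
   reactant energies computed under one set of conditions (mixing
   conditions raises). Δ_rG′ adds RT·Σ S_ij·ln c_i with water's
   activity fixed at 1 — water still contributes its formation energy
   to Δ_rG′⁰ (the bundled enolase reaction only reproduces its
   published value if it does) — and protons never appear, because the
   transform already holds pH constant.
3. **Network analysis.** In x = ln c every Δ_rG′ is affine, so
   feasibility, energy ranges, concentration tightening, directionality
   assignment and regulatory flagging are all linear programs over the
   box ln c_min ≤ x ≤ ln c_max.

## Constants and parameters

| Parameter | Default | Why |
|---|---|---|
| R | 8.31446×10⁻³ kJ·mol⁻¹·K⁻¹ | CODATA value; reproduces the conventional ionic-correction coefficient R·T·ln10·A = 2.91480 ≈ 2.91482 kJ/mol at 298.15 K to the precision that coefficient is usually quoted at. The coefficient is recomputed from A and T, so temperatures other than 25 °C are supported (the formation energies themselves carry no temperature dependence — no enthalpies are modeled). |
| Debye–Hückel A, B | 0.510651, 1.6 (L/mol)^1/2 | standard 25 °C values; validity 0.005–0.25 M. Outside that range the Conditions object records a warning and computes anyway — no better closed form is available at these ionic strengths. |
| F | 96.485 kJ·mol⁻¹·V⁻¹ | Faraday constant for the nFΔΨ transport term. |
| ε (strictness margin) | 10⁻⁶ kJ/mol | LPs cannot express strict inequalities; fixed directions are imposed as Δ_rG′ ≤ −ε (forward) or ≥ +ε. Configurable per problem. |
| Default concentration bounds | [10⁻⁶, 5×10⁻²] M | a generic physiological range for unmeasured metabolites (sub-µM detection limits up to tens of mM for central-carbon pools). Configurable; measured bounds are tagged separately from defaults in every result. |
| Regulatory threshold | Δ_rG′_max < −10 kJ/mol, strict | reactions this displaced from equilibrium are candidate sites of genetic/allosteric control. Configurable. |

Reference conventions: formation energies may be relative (the bundled
fixture sets NAD ≡ 0 and expresses NADH against it). The species table
carries a `reference_group` tag so a redox pair cannot silently mix
conventions; values within one group are only meaningful relative to
each other.

## Design choices where the design was open

- **Sign conventions in transport.** Stoichiometric coefficients of
  transported species are oriented destination-minus-origin, and ΔΨ is
  destination potential minus origin potential. Reversing a transporter
  negates n and every s_i but keeps ΔΨ, which is a property of the
  membrane, not of the reaction direction; this makes the transport
  term antisymmetric under reversal, as it must be. The pH term pairs
  each transported species with the transformed energy and pH (and
  temperature) of its *own* compartment; this is the reading that makes
  the term vanish when both compartments share conditions.
- **Ranging semantics.** When computing a reaction's feasible
  [Δ_rG′_min, Δ_rG′_max], its own sign constraint stays active: the
  range describes the feasible set as constrained, not a relaxation.
  `dg_range(..., keep_own_sign=False)` gives the relaxed variant.
- **Directionality fixed point.** Assignment sweeps all initially
  reversible reactions, turns a definite-sign range into a fixed
  direction, and repeats until nothing changes (bounded by the reaction
  count; exceeding it is reported as an invariant violation). Because
  each new constraint is implied by the range that produced it, the
  feasible set never shrinks during assignment, and re-checking
  feasibility afterwards must succeed — asserted in the tests.
- **Infeasibility certificates.** On infeasibility the checker returns
  an irreducible subset of the sign/ratio constraints (deletion
  filtering) that is already infeasible under the box bounds, naming
  the reactions involved; constant-energy reactions that violate their
  own sign constraint are certified without touching the solver.
- **Energy uncertainty.** Optionally, each reaction's Δ_rG′⁰ can be
  relaxed to an interval ±err via a bounded slack variable. Off by
  default: the plain formulation treats standard energies as exact.
- **Curation passes.** Two standard model clean-ups are provided but
  never applied implicitly: lumping opposite-direction isozyme pairs
  into one reversible reaction (leaving them separate pins the network
  to the equilibrium point of that pair), and pooling tagged aqueous
  CO₂ species (CO₂, HCO₃⁻, CO₃²⁻, H₂CO₃) into a single CO2tot reactant
  with water added to rebalance oxygen.
- **Group tables are data.** Ring and similar structural corrections
  are ordinary named groups (e.g. ">CH- (ring)"), not special-cased
  code; fuller published tables load from TSV. The bundled origin
  constants are treated as plain additive terms.
- **Interchange formats.** Bespoke TSV/JSON is the interchange (species
  tables, equation-string models, bounds, per-compartment conditions).
  Readers reject malformed rows by number, accept Unicode minus signs,
  and honor a `# units: J/mol` header declaration. All internal
  energies are kJ/mol.
- **Flow-force parameterization.** The bundled contrasting parameter
  sets share v_s^max = 100 and C = 10 mM and vary only the backward
  parameters: the reversible set (v_p^max = 100, K_s = K_p = 1 mM) has
  equal capacities, giving the symmetric curve whose proportional
  regime v = L·A is widest; the irreversible set (v_p^max = 1,
  K_p = 10 mM) saturates its denominator early and becomes
  linear-with-offset. The ratio v_s^max/v_p^max in the rate law is the
  form consistent with re-deriving the expression from reversible
  Michaelis–Menten kinetics plus the Haldane relation under
  C_s + C_p = C. L is exposed analytically as
  1/(RT·(K_s/C + 1 + (v_s/v_p)(K_p/C + 1))); figure-style curves are
  compared only through limits, slopes and orderings, never through
  values read off a plot.

## Numerical notes

- LP backend: scipy's HiGHS interior-point/simplex via `linprog`;
  statuses 0/2 map to feasible/infeasible, anything else raises a
  distinct `SolverError` so numerical failure is never reported as
  infeasibility. Results are deterministic for fixed inputs.
- Tolerances for matching published tables: ±0.02 kJ/mol for
  reactant-level formation energies and ±0.05 kJ/mol for reaction
  energies (tables print two decimals computed from unrounded
  intermediates); ±0.3 kJ/mol for group-contribution totals, whose
  printed per-group values are themselves rounded (the published
  per-group totals disagree with count×unit in the last digit, e.g.
  4×(−173.8) = −695.2 vs a printed −695.0 — tests assert against the
  recomputed products).
- The published PGK entry (+8.16 kJ/mol) is inconsistent with the
  formation-energy column it derives from, which yields −8.16; the
  fixture records the discrepancy and comparisons there are by
  magnitude.
- The flow-force expression is evaluated in its e^{−x} form for
  positive affinity and its e^{+x} form for negative, so sweeps are
  overflow-safe at any |A|.

## Synthetic networks and what the tests show

The toy-network generator builds networks whose feasibility status is
guaranteed by construction: feasible instances sample an interior
log-concentration witness first and derive standard energies that give
every sign-constrained reaction a 2–15 kJ/mol margin at the witness;
infeasible instances plant one unimolecular forward step whose standard
energy exceeds the best achievable pull of the bounds box by 25 kJ/mol.
Generation is deterministic per seed.

The LP machinery is validated against an independent dense log-grid
enumeration oracle on networks of ≤4 metabolites (default grid 21
points per axis). Because a grid can both miss thin feasible slivers
and miss optima between nodes, the oracle computes strict and
slack-relaxed admissibility (half-grid-step Lipschitz slack) and the
tests assert the provable sandwich strict ≤ LP ≤ relaxed + one grid
step; direction assignment is checked against exhaustive enumeration of
forward/backward patterns on 3-reaction networks, skipping the rare
instances the grid resolution cannot decide. Acceptance runs use 1000
oracle instances, 1000 classification instances and 250 enumeration
instances — sizes chosen so the whole suite exercises thousands of LPs
while staying desk-scale.

What passing these tests does *not* show: the generator produces small,
unit-coefficient, single-compartment networks with independent
box bounds; real metabolomes bring correlated measurements, shared
conserved moieties, transport steps and genome-scale dimensions, none
of which the synthetic ensemble emulates. The published genome-scale
case study's measured dataset is not public, so its specific energy
ranges are treated as format examples, not reproduction targets.

## Known limitations

- No Mg²⁺ or other metal-complex pseudoisomers (no binding data is
  modeled), and no temperature dependence of Δ_fG⁰ itself.
- No automatic molecular decomposition into groups; decompositions are
  inputs.
- No flux-space coupling (the MILP that ties directions to flux
  distributions is out of scope), and no SBML import — models enter via
  the TSV/JSON formats.
- The Debye–Hückel correction is used outside its stated validity range
  only with an explicit recorded warning.
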