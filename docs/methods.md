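# Methods

## The problem

Glycerol is an unusually reduced carbon source (degree of reduction per
carbon κ = 14/3 ≈ 4.67, against ≈ 4.3 for average cell mass of composition
CH₁.₉O₀.₅N₀.₂ and 4.0 for glucose). Making biomass from glycerol therefore
*releases* reducing equivalents, and a fermenting cell — with no external
electron acceptor — must re-absorb them using internal sinks. *E. coli*
has two such sinks: synthesis of 1,2-propanediol (κ = 5.33, an
electron-richer product than the substrate) and, when hydrogenase
reversibility permits (alkaline pH), reduction of protons to H₂ fed by the
menaquinol that the respiratory-type GlpK→GlpABC dissimilation route
deposits in the quinone pool. This package implements the constraint-based
machinery to analyse those modes: flux balance analysis (FBA), flux
variability analysis (FVA), production envelopes, curation recipes,
gene-knockout scenarios, and electron-balance audits.

## Model and procedure

A metabolic model is the linear steady-state world **S·v = 0** with flux
bounds `lb ≤ v ≤ ub` and optional extra linear couplings (used for fixed
product yields and flux-ratio caps). FBA maximizes a linear objective
(biomass flux, h⁻¹); FVA minimizes and maximizes each flux subject to the
objective staying at a fraction (default 1.0) of its optimum; a production
envelope sweeps a growth-level floor from 0 to μ_max and records the
feasible product-flux interval at each level.

Key conventions:

- Exchange reactions are written `metabolite →` with a single −1 entry:
  negative flux is uptake (glycerol uptake −20 mmol gCDW⁻¹ h⁻¹), positive
  is secretion.
- Non-growth-associated ATP maintenance (ATPM) is an ordinary reaction
  with both bounds set to 3.15 mmol gCDW⁻¹ h⁻¹, keeping the LP uniform.
- Product-yield constraints are equalities `v_product + yield·v_substrate
  = 0` (acetate 0.012, succinate 0.015 mol mol⁻¹ glycerol): the observed
  yields are imposed, not just capped. An `equality=False` option gives ≤.
- The fructose-phosphate-bypass cap is the inequality
  `v_FSA + 0.2·v_EX_glyc ≤ 0`, i.e. at most 20% of the glycerol transport
  magnitude.
- Gene–protein–reaction rules are boolean expressions (identifiers, AND,
  OR, parentheses, case-insensitive keywords); a deletion disables every
  reaction whose rule evaluates false.

## The core synthetic model

`glycferm.fixtures.build_core_model` constructs a 62-reaction,
51-metabolite, 46-gene anaerobic network containing: the three glycerol
dissimilation routes (GldA→DhaKLM with its PEP→pyruvate coupling;
GlpK→GlpABC feeding menaquinol; the FsaA/FsaB fructose-phosphate bypass);
an ATP-dependent DHA kinase shipped with (0,0) bounds as an engineering
plug-in; the methylglyoxal route to 1,2-propanediol (2 NADH per mole);
PFL/AdhE/Pta-AckA/FHL and the quinone-coupled reversible hydrogenase
(HYD1/HYD2, rule `hyaB or (hybA and hybC)`; FHL is `hycE and fdhF`); the
full PEP node (PykA/PykF, PpsA with 2 ATP equivalents, Ppc, reversible
Pck, decarboxylating malic enzymes); the four-isozyme FBPase (`fbp or
glpX or yggF or ybhA`); a truncated TCA branch to α-ketoglutarate; ATPM;
and a parameterized biomass drain. Every metabolite carries an elemental
formula and every internal reaction balances C, H, O, N, P, S, so flux
solutions can be audited electron-by-electron.

### Biomass drain

Defaults (mmol per gram biomass): F6P 0.2, GAP 0.1, 3PG 1.5, PEP 0.7,
PYR 2.8, OAA 1.8, AKG 1.1, AcCoA 0.9 (CoA returned), formate (C1 units)
2.0, NH₄ 8.0, growth-associated ATP 40 (hydrolysed with water to
ADP + Pi + H⁺), and a net release of δ = 1.5 NADH. These approximate
standard precursor demands at the level of a reduced network; they are
*not* fitted to genome-scale growth rates, and the fixture's absolute
growth rates are pattern-level quantities only. δ > 0 is enforced: it
encodes the premise that cell synthesis from glycerol nets out reducing
equivalents, and any positive value preserves the qualitative behaviour.

Two stoichiometric closure rules keep the redox and one-carbon ledgers
exactly decomposable, which is what lets the test suite assert the mode
signatures to 1e−6 rather than "approximately":

1. **Fumarate reduction is lumped through the NADH pool** (MDH plus an
   NADH-coupled fumarate reduction step; two NADH per succinate from OAA,
   the correct total electron count). In the organism FRD draws on
   menaquinol; lumping its small, yield-fixed electron demand (0.030 mol
   mol⁻¹ glycerol) into NADH leaves the menaquinol pool as the *exclusive*
   conduit from GlpABC to the reversible hydrogenase, so GlpABC flux and
   net HYD flux coincide exactly at the optimum instead of differing by
   the succinate term.
2. **Each C2 (acetyl) unit consumed by biosynthesis is paired with
   formate-derived C1 units.** Biosynthesis genuinely consumes C1 units
   (purine rings, formylmethionine); setting the biomass formate drain
   equal to the total acetyl demand (direct AcCoA plus the acetyl consumed
   by citrate synthase en route to AKG) closes the formate ledger at the
   acetyl level, so H₂ from formate splitting equals ethanol + acetate
   secretion exactly in the 1,2-PDO mode.

### The formate valve

The formate exchange is present but shipped closed. Without membrane
energetics (deliberately out of scope — no proton-motive force, no ΔpH),
exporting formate and splitting it via FHL are indistinguishable to the
LP: identical carbon and electron export. An open valve would make the
formate fate degenerate and destroy the uniqueness of the H₂ flux at the
optimum. Closing it encodes the observed behaviour (formate is split;
hydrogen evolves) as a structural choice; scenarios for FHL-negative
strains (ΔhycE, ΔfdhF) re-open the valve, reproducing formate
accumulation with essentially unchanged growth.

### Other fixture choices

- **Malic enzymes are irreversible toward pyruvate** (their physiological
  decarboxylating direction). Otherwise an MDH + Pck detour would
  regenerate PEP from pyruvate and defeat the prediction that removing
  PEP synthetase in the absence of a PEP-decoupled dissimilation route
  abolishes growth.
- **Pck is reversible** and Ppc present; the network chooses between
  them. (At the base optimum Pck runs in the carboxylating, ATP-forming
  direction — the anaplerotic role the deletion data point to.)
- **NADPH is lumped with NADH**; no transhydrogenase. The redox argument
  is carrier-agnostic at this resolution.
- **PDH is present but constrained off by the shipped base recipe**
  (it is strongly NADH-inhibited in the reduced intracellular state of
  glycerol fermentation). With PDH free, pyruvate oxidation could bolt a
  spurious NADH source onto the GlpK route and mask the essentiality of
  GldA→DhaKLM. The constraint is an editable, logged recipe step, not a
  property of the model object.
- **NADH→quinone transfer (NDH-2) and the NADH-linked G3P shuttle arm
  ship in the raw model** and are removed by the base recipe, mirroring
  the curation story: they are expressed under respiratory, not
  fermentative, conditions, and leaving them in lets electrons shuttle
  between NAD(P)H and the quinone pool. `detect_futile_cycles` (closing
  all exchanges, relaxing forced fluxes toward zero, and running FVA)
  demonstrates the loop on an augmented variant and its disappearance
  after removal; cycle removal itself is always an explicit recipe step.
- The aerobic GlpD reaction is present with (0,0) bounds (and a dead-end
  ubiquinone pair), for completeness of the dissimilation picture.
- 1,2-PDO export is a zero-cost exchange.

## Scenarios

The shipped registry (`glycferm.registry.core_scenarios`) provides:
`h2_mode` (base case), `pdo_mode` (reversible hydrogenase removed),
`fp_capped` (base + 20% bypass cap), capped variants of both modes, the
six-entry PEP-node pathway-removal matrix, and a ~30-entry single/double
deletion screen. The matrix and screen run in the capped ("refined")
context: without the cap the FP bypass substitutes for DhaKLM at equal
ATP yield and deletion phenotypes of the PEP-coupled route vanish.
INFEASIBLE programs are reported as growth 0 with status preserved —
under fixed yield couplings and maintenance ATP, infeasibility *is* the
no-growth phenotype.

## Numerical choices

- LP backend: scipy's HiGHS (`scipy.optimize.linprog`), primal/dual
  feasibility tolerance 1e−9, behind a minimal backend contract
  (equalities, inequalities, bounds; optimal/infeasible/unbounded).
- Assertion tolerance in tests: 1e−6; growth-coupling threshold 1e−6.
- FVA fixes the objective with an inequality floor (≥ fraction·optimum),
  never an equality; fraction defaults to 1.0.
- Degenerate alternate optima are expected (the dissimilation split is
  genuinely degenerate); `solve_fba` returns one arbitrary vertex and all
  scientific claims are asserted through FVA ranges or through fluxes
  that are provably unique at the optimum.
- FVA min/max pairs are clamped to `min ≤ max` when solver jitter on a
  pinned flux inverts them by <1e−9.
- UNBOUNDED status is surfaced distinctly: it almost always means a
  missing exchange cap or an unremoved internal cycle.

## What the synthetic model does and does not show

The fixture reproduces the *structure* of the analysis: which products
are growth-coupled in which mode, the exact GlpABC–hydrogenase coupling,
the H₂/ethanol stoichiometry without the reversible hydrogenase, the
PEP-node deletion matrix including the zero-growth cell and its rescue by
an ATP-dependent DHA kinase, and electron-balance closure on every
optimum. Its absolute fluxes and growth rates are *not* those of the
genome-scale model: the biomass equation is a reduced surrogate, there is
no maintenance partitioning beyond ATPM, no compartmentalization, no
membrane energetics, and no kinetic or regulatory effects (the pH
dependence of hydrogenase reversibility enters only as scenario on/off).
Passing the pattern suite therefore says the method and network logic are
right, not that the fixture predicts culture behaviour quantitatively.
Full-scale growth-rate reproduction is available through the shipped
BiGG-identifier recipe when a local copy of the published iJO1366 model
is provided (see README); the mapping of the curation narrative onto
specific genome-scale reaction ids is kept in that recipe file, where it
can be audited and edited.

## Known limitations

- SBML export covers models without coupling constraints (the fbc package
  has no such construct); curated models round-trip through the JSON
  dialect.
- `detect_futile_cycles` groups flagged reactions by shared metabolites,
  which can merge distinct loops touching a common currency metabolite;
  it is advisory only.
- The vertex-enumeration oracle used in tests is exponential and limited
  to the ≤6-reaction random models; it exists to check the LP path, not
  for production use.
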