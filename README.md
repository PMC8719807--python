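# glycferm

Constraint-based analysis of **fermentative glycerol metabolism in
*Escherichia coli***: flux balance analysis (FBA), flux variability
analysis (FVA), production envelopes, declarative model-curation recipes,
gene-knockout scenario screens, and degree-of-reduction electron-balance
audits — built around a fully elementally balanced core model of the
anaerobic glycerol fermentation network.

## The scientific problem

Glycerol is more reduced than cell mass: its degree of reduction per
carbon is κ = 4.67 (κ = Σ valence·count / #C with C=+4, H=+1, O=−2,
N=−3), versus ≈ 4.3 for biomass of average composition CH₁.₉O₀.₅N₀.₂ and
4.0 for glucose. Growing on glycerol therefore *generates* reducing
equivalents, and without an external electron acceptor the cell must
absorb them internally. *E. coli* can do this two ways:

- **H₂ evolution mode** (alkaline pH): part of the glycerol flux runs
  through the respiratory-type GlpK→GlpABC route, depositing electrons in
  the menaquinone pool, from which a reversible hydrogenase reduces
  protons to H₂.
- **1,2-propanediol mode** (acidic pH): the electron-richer product
  1,2-PDO (κ = 5.33) is synthesized from DHAP at the cost of carbon and
  ATP.

Either way, the NADH-generating GldA→DhaKLM route is essential — and
because DhaKLM phosphorylates DHA with PEP, every mole of glycerol
dissimilated this way converts one PEP to pyruvate, a stoichiometric
cycle that starves the PEP node and makes PEP synthetase, Pck
anaplerosis, the fructose-phosphate bypass and multiple FBPases matter in
ways unique to fermentative glycerol metabolism. The package's scenario
machinery reproduces all of these effects as FBA/FVA properties.

## Worked example

Solve the acidic-mode scenario (reversible hydrogenase removed) on the
shipped core model:

```sh
$ glycferm fba --scenario pdo_mode --out demo
growth rate: 0.1816 h^-1 (fluxes.tsv, summary.json in demo)
$ cat demo/summary.json
{
 "status": "OPTIMAL",
 "growth_rate_per_h": 0.18164414414414412,
 "glycerol_uptake": -20.0,
 "product_yields_mol_per_mol_glycerol": {
  "EX_etoh_e": 0.6465624999999999,
  "EX_h2_e": 0.6585624999999999,
  "EX_for_e": -0.0,
  "EX_ac_e": 0.012,
  "EX_succ_e": 0.015,
  "EX_pdo12_e": 0.23198254504504484
 },
 "config": "cbb4dded3360"
}
```

Reading the numbers: glycerol uptake is pinned at 20 mmol gCDW⁻¹ h⁻¹;
ethanol dominates (0.65 mol/mol); acetate and succinate sit exactly on
their imposed experimental yields (0.012, 0.015); 1,2-PDO is forced on
(0.23 mol/mol — the only remaining electron sink, hence growth-coupled);
and H₂ equals ethanol + acetate (0.6466 + 0.012 = 0.6586) because without
the reversible hydrogenase every H₂ stems from formate splitting, one
formate per acetyl unit. Running `--scenario h2_mode` instead gives a
higher growth rate (0.3974 h⁻¹) with H₂ *above* the formate-derived
level and zero 1,2-PDO — the hydrogen-venting mode.

Other verbs: `fva`, `envelope --product EX_etoh_e`, `ko-scan --select
keio_` (the deletion screen), `curate`, `audit-redox` (electron ledger of
an optimum), `build-fixture`. The same functionality is available as a
library:

```python
from glycferm.fixtures import build_core_model
from glycferm.registry import core_scenarios
from glycferm.scenarios import build_scenario_model
from glycferm.lp import solve_fva

model = build_scenario_model(build_core_model(), core_scenarios()["h2_mode"])
fva = solve_fva(model, fraction_of_optimum=1.0, reaction_ids=["G3PD", "HYD", "FSA"])
```

## Layout

- `src/glycferm/model.py`, `formula.py`, `io.py` — model types,
  validation, stoichiometric matrix, JSON/SBML I/O
  (see `docs/model_schema.md`)
- `src/glycferm/lp.py` — FBA / FVA / envelopes over an LP backend contract
- `src/glycferm/curation.py` — yield fixes, removals, ratio caps, futile
  cycle detection, YAML recipes
- `src/glycferm/scenarios.py`, `generule.py` — GPR rules, gene deletions,
  scenario registry, knockout matrices
- `src/glycferm/redox.py` — κ calculator and electron-balance audits
- `src/glycferm/fixtures.py` — the core network, toy LPs, random models
- `src/glycferm/data/` — shipped recipes, scenario registry, and the
  checked-in core model (regenerated by
  `scripts/regenerate_core_model.py`)
- `docs/methods.md` — modelling assumptions, parameters and limitations
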