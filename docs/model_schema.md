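# JSON model dialect

The package's native exchange format. It round-trips exactly
(`read_model(write_model(m))` is structurally identical to `m`) and is
the only format that carries coupling constraints.

```json
{
 "id": "glycferm_core",
 "metabolites": [
  {
   "id": "glyc_c",
   "name": "glycerol",
   "compartment": "c",
   "formula": {"C": 3, "H": 8, "O": 3}
  }
 ],
 "reactions": [
  {
   "id": "GLYDH",
   "name": "glycerol dehydrogenase (GldA)",
   "stoichiometry": {"glyc_c": -1.0, "nad_c": -1.0,
                     "dha_c": 1.0, "nadh_c": 1.0, "h_c": 1.0},
   "lower_bound": 0.0,
   "upper_bound": 1000.0,
   "gene_rule": "gldA",
   "subsystem": ""
  }
 ],
 "objective": {"BIOMASS": 1.0},
 "couplings": [
  {
   "terms": {"EX_ac_e": 1.0, "EX_glyc_e": 0.012},
   "relation": "EQ",
   "rhs": 0.0,
   "tag": "yield:EX_ac_e:EX_glyc_e"
  }
 ]
}
```

Field notes:

- `metabolites[].formula` — element → count mapping (non-integer counts
  allowed, e.g. a biomass formula); `null` or absent when unknown.
  Elements are restricted to C, H, O, N, P, S.
- `reactions[].stoichiometry` — metabolite id → signed coefficient;
  negative = consumed. Exchange reactions have exactly one entry.
- `reactions[].gene_rule` — boolean expression over gene identifiers with
  `and` / `or` / parentheses (case-insensitive keywords); empty string
  means always active.
- Bounds are mmol gCDW⁻¹ h⁻¹ (the biomass reaction's flux is h⁻¹).
- `couplings[].relation` — one of `EQ`, `LE`, `GE`; `terms` maps reaction
  ids to coefficients of a linear constraint `Σ coeff·v (relation) rhs`.
- `couplings[].tag` — identity of the constraint for the idempotency
  guard (re-applying a recipe that would duplicate a tag is rejected).

Required keys: `metabolites`, `reactions`. `objective` and `couplings`
default to empty. Unknown keys are rejected nowhere (forward-compatible
readers), but nothing else is interpreted.

SBML Level 3 (+fbc, for flux bounds, chemical formulas, gene-product
associations and the active objective) is supported for reading —
including published BiGG genome-scale models — and for writing models
without couplings.
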