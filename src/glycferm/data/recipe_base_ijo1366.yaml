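# Base-case curation recipe against the published iJO1366 genome-scale
# model (BiGG identifiers), for optional full-scale reproduction. The
# iJO1366 SBML file is not shipped; obtain it from the BiGG model
# repository and see tests/test_acceptance.py.
#
# The published account names enzymes rather than reaction ids; the id
# lists below are this package's mapping onto iJO1366 and are kept in
# config (not code) so they stay auditable and editable:
#  - NADH:ubiquinone oxidoreductase I and II -> NADH16pp / NADH17pp /
#    NADH18pp (proton-pumping nuo complex and ndh, all quinone variants),
#    plus NADH5 where present.
#  - malate/fumarate electron cycling -> quinone-linked malate
#    dehydrogenases MDH2 / MDH3 (cycle against NADH-linked MDH).
#  - glycolate/glyoxylate electron cycling -> quinone-linked glycolate
#    oxidases GLYCTO2 / GLYCTO3 / GLYCTO4 (cycle against NAD(P)H-linked
#    glyoxylate reductases).
#  - reversible menaquinol-coupled hydrogenase -> HYD2pp (removed only in
#    the 1,2-PDO scenario, not here).
name: base_ijo1366
id_map:
  glycerol_exchange: EX_glyc_e
  acetate_exchange: EX_ac_e
  succinate_exchange: EX_succ_e
  atpm: ATPM
  reversible_hydrogenase: HYD2pp
  fp_bypass_aldolase: F6PA
  pdh: PDH
medium:
  atpm_reaction: atpm
  atpm_flux: 3.15
  exchange_bounds:
    glycerol_exchange: [-20.0, 0.0]
    # no external electron acceptors
    EX_o2_e: [0.0, 1000.0]
    EX_no3_e: [0.0, 1000.0]
    EX_no2_e: [0.0, 1000.0]
    EX_tmao_e: [0.0, 1000.0]
    EX_dmso_e: [0.0, 1000.0]
    # glycerol is the only limiting carbon source
    EX_glc__D_e: [0.0, 1000.0]
steps:
  - op: FIX_YIELD
    product_exchange: acetate_exchange
    substrate_exchange: glycerol_exchange
    yield: 0.012
  - op: FIX_YIELD
    product_exchange: succinate_exchange
    substrate_exchange: glycerol_exchange
    yield: 0.015
  - op: REMOVE_REACTIONS
    ids: [NADH16pp, NADH17pp, NADH18pp]
    reason: NADH-to-quinone transfer not expressed without external acceptors
  - op: REMOVE_REACTIONS
    ids: [MDH2, MDH3]
    reason: malate/fumarate electron cycling against NADH-linked MDH
  - op: REMOVE_REACTIONS
    ids: [GLYCTO2, GLYCTO3, GLYCTO4]
    reason: glycolate/glyoxylate electron cycling against NAD(P)H reductases
  - op: SET_BOUNDS
    reaction: pdh
    lo: 0.0
    hi: 0.0
    reason: PDH negligible under glycerol fermentation (NADH inhibition)
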