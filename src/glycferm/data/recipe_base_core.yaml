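# Base-case curation recipe for the shipped core glycerol-fermentation model.
#
# Anaerobic minimal medium with glycerol as the only limiting nutrient
# (uptake bounded at -20 mmol gCDW-1 h-1), ATP maintenance fixed at 3.15,
# acetate and succinate secretion fixed to experimentally observed molar
# yields, NADH-to-quinone electron transfer and the G3P redox shuttle
# removed (not expressed without external electron acceptors), and PDH
# constrained off (NADH-inhibited under the highly reduced intracellular
# state of glycerol fermentation).
name: base_core
id_map:
  glycerol_exchange: EX_glyc_e
  acetate_exchange: EX_ac_e
  succinate_exchange: EX_succ_e
  formate_exchange: EX_for_e
  atpm: ATPM
  nadh_quinone_transfer: NDH2
  g3p_redox_shuttle: G3PD_NADH
  pdh: PDH
  reversible_hydrogenase: HYD
  fp_bypass_aldolase: FSA
  atp_dha_kinase: DHAK_ATP
medium:
  atpm_reaction: atpm
  atpm_flux: 3.15
  exchange_bounds:
    glycerol_exchange: [-20.0, 0.0]
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
    ids: [nadh_quinone_transfer, g3p_redox_shuttle]
    reason: >-
      NADH-to-quinone electron transfer is induced by external electron
      acceptors and not expressed under fermentative conditions; leaving
      these reactions in lets internal cycles shift electrons between
      NAD(P)H and the quinone pool.
  - op: SET_BOUNDS
    reaction: pdh
    lo: 0.0
    hi: 0.0
    reason: >-
      pyruvate dehydrogenase carries negligible flux under glycerol
      fermentation (NADH inhibition); pyruvate conversion proceeds via
      pyruvate formate-lyase.
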