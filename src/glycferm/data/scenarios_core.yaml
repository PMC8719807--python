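# Scenario registry for the core glycerol-fermentation model.
#
# h2_mode      — alkaline, H2-enabled fermentation (base case).
# pdo_mode     — acidic, 1,2-PDO-enabled fermentation: the reversible
#                menaquinol-coupled hydrogenase is removed.
# fp_capped    — H2 mode with the fructose-phosphate bypass capped at 20%
#                of the incoming glycerol transport flux (refined model).
# *_capped     — capped variants used for the pathway-removal matrix and
#                the deletion screen (the refined-model context).
scenarios:
  - name: h2_mode
    recipe: base
    description: H2-enabled base case (alkaline)

  - name: pdo_mode
    recipe: base
    description: 1,2-PDO-enabled mode (acidic; no reversible hydrogenase)
    extra_edits:
      - op: REMOVE_REACTIONS
        ids: [reversible_hydrogenase]
        reason: hydrogenase reversibility unfavourable at acidic pH

  - name: fp_capped
    recipe: base
    description: H2 mode, FP bypass capped at 20% of glycerol transport
    extra_edits:
      - &fp_cap
        op: CAP_RATIO
        capped_reaction: fp_bypass_aldolase
        reference_reaction: glycerol_exchange
        fraction: 0.20

  - name: h2_mode_capped
    recipe: base
    description: refined H2 mode (same edits as fp_capped)
    extra_edits: [*fp_cap]

  - name: pdo_mode_capped
    recipe: base
    description: refined 1,2-PDO mode
    extra_edits:
      - *fp_cap
      - op: REMOVE_REACTIONS
        ids: [reversible_hydrogenase]
        reason: hydrogenase reversibility unfavourable at acidic pH

  # ------------------------------------------------------------------
  # pathway-removal x PEP-node deletion matrix (refined model context)
  # ------------------------------------------------------------------
  - name: fig5b_base
    recipe: base
    extra_edits: [*fp_cap]
    description: all dissimilation routes present

  - name: fig5b_no_pyk
    recipe: base
    extra_edits: [*fp_cap]
    gene_deletions: [pykA, pykF]
    description: pyruvate kinase removed

  - name: fig5b_no_decoupled
    recipe: base
    extra_edits:
      - &no_decoupled
        op: REMOVE_REACTIONS
        ids: [GLPK, G3PD, FSA]
        reason: PEP-decoupled dissimilation routes (GlpK-GlpABC, FP bypass) removed
    description: only the PEP-coupled GldA-DhaKLM route remains

  - name: fig5b_no_decoupled_no_pyk
    recipe: base
    extra_edits: [*no_decoupled]
    gene_deletions: [pykA, pykF]
    description: PEP-coupled route only, pyruvate kinase removed

  - name: fig5b_no_decoupled_no_pps
    recipe: base
    extra_edits: [*no_decoupled]
    gene_deletions: [ppsA]
    description: PEP-coupled route only, PEP synthetase removed (no growth)

  - name: fig5b_no_decoupled_no_pps_atpdhak
    recipe: base
    extra_edits:
      - *no_decoupled
      - op: SET_BOUNDS
        reaction: atp_dha_kinase
        lo: 0.0
        hi: 1000.0
        reason: ATP-dependent (PEP-independent) DHA kinase plug-in enabled
    gene_deletions: [ppsA]
    description: rescue of the no-decoupled ppsA-deleted background

  # ------------------------------------------------------------------
  # single/combined gene deletion screen (refined model context)
  # ------------------------------------------------------------------
  - {name: keio_gldA,      recipe: base, extra_edits: [*fp_cap], gene_deletions: [gldA]}
  - {name: keio_dhaK,      recipe: base, extra_edits: [*fp_cap], gene_deletions: [dhaK]}
  - {name: keio_glpK,      recipe: base, extra_edits: [*fp_cap], gene_deletions: [glpK]}
  - {name: keio_fsaA,      recipe: base, extra_edits: [*fp_cap], gene_deletions: [fsaA]}
  - {name: keio_fsaB,      recipe: base, extra_edits: [*fp_cap], gene_deletions: [fsaB]}
  - {name: keio_fsaA_fsaB, recipe: base, extra_edits: [*fp_cap], gene_deletions: [fsaA, fsaB]}
  - {name: keio_pykA,      recipe: base, extra_edits: [*fp_cap], gene_deletions: [pykA]}
  - {name: keio_pykF,      recipe: base, extra_edits: [*fp_cap], gene_deletions: [pykF]}
  - {name: keio_pykA_pykF, recipe: base, extra_edits: [*fp_cap], gene_deletions: [pykA, pykF]}
  - {name: keio_ppsA,      recipe: base, extra_edits: [*fp_cap], gene_deletions: [ppsA]}
  - {name: keio_ppsA_glpK, recipe: base, extra_edits: [*fp_cap], gene_deletions: [ppsA, glpK]}
  - {name: keio_ppc,       recipe: base, extra_edits: [*fp_cap], gene_deletions: [ppc]}
  - {name: keio_pckA,      recipe: base, extra_edits: [*fp_cap], gene_deletions: [pckA]}
  - {name: keio_maeA,      recipe: base, extra_edits: [*fp_cap], gene_deletions: [maeA]}
  - {name: keio_maeB,      recipe: base, extra_edits: [*fp_cap], gene_deletions: [maeB]}
  - {name: keio_fbp,       recipe: base, extra_edits: [*fp_cap], gene_deletions: [fbp]}
  - {name: keio_glpX,      recipe: base, extra_edits: [*fp_cap], gene_deletions: [glpX]}
  - {name: keio_yggF,      recipe: base, extra_edits: [*fp_cap], gene_deletions: [yggF]}
  - {name: keio_ybhA,      recipe: base, extra_edits: [*fp_cap], gene_deletions: [ybhA]}
  - {name: keio_fbp_glpX,  recipe: base, extra_edits: [*fp_cap], gene_deletions: [fbp, glpX]}
  - {name: keio_fbp_yggF,  recipe: base, extra_edits: [*fp_cap], gene_deletions: [fbp, yggF]}
  - {name: keio_fbp_ybhA,  recipe: base, extra_edits: [*fp_cap], gene_deletions: [fbp, ybhA]}
  - {name: keio_glpX_yggF, recipe: base, extra_edits: [*fp_cap], gene_deletions: [glpX, yggF]}
  - {name: keio_glpX_ybhA, recipe: base, extra_edits: [*fp_cap], gene_deletions: [glpX, ybhA]}
  - {name: keio_yggF_ybhA, recipe: base, extra_edits: [*fp_cap], gene_deletions: [yggF, ybhA]}
  - {name: keio_adhE,      recipe: base, extra_edits: [*fp_cap], gene_deletions: [adhE]}
  - {name: keio_hyaB,      recipe: base, extra_edits: [*fp_cap], gene_deletions: [hyaB]}
  - {name: keio_hybA,      recipe: base, extra_edits: [*fp_cap], gene_deletions: [hybA]}
  - {name: keio_hybC,      recipe: base, extra_edits: [*fp_cap], gene_deletions: [hybC]}
  # FHL-negative strains accumulate and secrete formate; their scenarios
  # open the formate valve accordingly.
  - name: keio_hycE
    recipe: base
    gene_deletions: [hycE]
    extra_edits:
      - *fp_cap
      - &open_formate
        op: SET_BOUNDS
        reaction: formate_exchange
        lo: 0.0
        hi: 1000.0
        reason: FHL-negative strains secrete formate
  - name: keio_fdhF
    recipe: base
    gene_deletions: [fdhF]
    extra_edits: [*fp_cap, *open_formate]
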