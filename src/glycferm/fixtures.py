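"""Synthetic model construction: the core glycerol-fermentation network,
hand-checkable toy LPs, and seeded random models for oracle tests.

The core model is a reduced anaerobic *E. coli* network built around the
three glycerol dissimilation routes — GldA→DhaKLM (NADH-generating,
PEP-consuming), GlpK→GlpABC (menaquinol-generating) and the fructose
phosphate bypass (FsaA/FsaB) — together with the 1,2-propanediol branch,
the mixed-acid fermentation block (PFL, AdhE, Pta-AckA, FHL), the
quinone-coupled reversible hydrogenase, the full PEP node (pyruvate
kinases, PEP synthetase, Ppc, Pck, malic enzymes), the FBPase isozyme set,
a truncated TCA branch to α-ketoglutarate, ATP maintenance, and a
parameterized biomass drain that net-generates reducing equivalents on
glycerol.

Every cytosolic metabolite carries an elemental formula and every internal
reaction is balanced for C, H, O, N (and P, S), so flux solutions can be
audited at the electron level.

Two design choices keep the redox ledger exactly decomposable and are
documented in docs/methods.md: fumarate reduction is lumped through the
NADH pool (2 NADH per succinate from OAA), leaving the menaquinol pool as
the exclusive GlpABC→hydrogenase conduit; and the biomass drain pairs each
acetyl (AcCoA) unit with one formate-derived C1 unit, closing the
one-carbon ledger at the acetyl level.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .formula import ElementalFormula
from .model import MetabolicModel, Metabolite, Reaction

# BiGG-style elemental formulas (charged-species conventions, which balance
# element-wise when free protons are carried explicitly)
_FORMULAS = {
    "glyc": "C3H8O3", "dha": "C3H6O3", "dhap": "C3H5O6P", "g3p": "C3H7O6P",
    "gap": "C3H5O6P", "f6p": "C6H11O9P", "fdp": "C6H10O12P2", "pg3": "C3H4O7P",
    "pep": "C3H2O6P", "pyr": "C3H3O3", "oaa": "C4H2O5", "mal": "C4H4O5",
    "fum": "C4H2O4", "succ": "C4H4O4", "cit": "C6H5O7", "icit": "C6H5O7",
    "akg": "C5H4O5", "accoa": "C23H34N7O17P3S", "coa": "C21H32N7O16P3S",
    "etoh": "C2H6O", "ac": "C2H3O2", "for": "CHO2", "co2": "CO2", "h2": "H2",
    "mg": "C3H4O2", "pdo12": "C3H8O2", "nad": "C21H26N7O14P2",
    "nadh": "C21H27N7O14P2", "atp": "C10H12N5O13P3", "adp": "C10H12N5O10P2",
    "amp": "C10H12N5O7P", "pi": "HO4P", "nh4": "H4N", "h2o": "H2O", "h": "H",
    "mqn8": "C51H72O2", "mql8": "C51H74O2", "q8": "C49H74O4", "q8h2": "C49H76O4",
}

_NAMES = {
    "glyc": "glycerol", "dha": "dihydroxyacetone", "dhap": "DHA phosphate",
    "g3p": "glycerol 3-phosphate", "gap": "glyceraldehyde 3-phosphate",
    "f6p": "fructose 6-phosphate", "fdp": "fructose 1,6-bisphosphate",
    "pg3": "3-phosphoglycerate", "pep": "phosphoenolpyruvate", "pyr": "pyruvate",
    "oaa": "oxaloacetate", "mal": "L-malate", "fum": "fumarate",
    "succ": "succinate", "cit": "citrate", "icit": "isocitrate",
    "akg": "alpha-ketoglutarate", "accoa": "acetyl-CoA", "coa": "coenzyme A",
    "etoh": "ethanol", "ac": "acetate", "for": "formate", "co2": "CO2",
    "h2": "hydrogen", "mg": "methylglyoxal", "pdo12": "1,2-propanediol",
    "nad": "NAD+", "nadh": "NADH", "atp": "ATP", "adp": "ADP", "amp": "AMP",
    "pi": "phosphate", "nh4": "ammonium", "h2o": "water", "h": "proton",
    "mqn8": "menaquinone 8", "mql8": "menaquinol 8",
    "q8": "ubiquinone 8", "q8h2": "ubiquinol 8",
}

#: external species (everything else is cytosolic)
_EXTERNAL = ["glyc", "etoh", "ac", "succ", "for", "co2", "h2", "pdo12",
             "pi", "nh4", "h2o", "h"]

INF = 1000.0


@dataclass
class FixtureManifest:
    """Parameters and expected shape of the core model.

    ``nadh_release`` (δ) is the net NADH released per unit biomass flux on
    top of the precursor-level surplus; the premise that growth on glycerol
    net-generates reducing equivalents requires δ > 0.
    """

    model_id: str = "glycferm_core"
    reaction_count: int = 62
    metabolite_count: int = 51
    gene_count: int = 46
    biomass: dict[str, float] = field(default_factory=lambda: {
        "f6p": 0.2, "gap": 0.1, "pg3": 1.5, "pep": 0.7, "pyr": 2.8,
        "oaa": 1.8, "akg": 1.1, "accoa": 0.9, "c1_formate": 2.0,
        "nh4": 8.0, "gam_atp": 40.0,
    })
    nadh_release: float = 1.5  # δ
    seed: int = 0

    def validate(self) -> None:
        if self.nadh_release <= 0:
            raise ValueError(
                "manifest nadh_release (δ) must be positive: growth on "
                "glycerol must net-generate reducing equivalents"
            )
        for k, v in self.biomass.items():
            if v < 0:
                raise ValueError(f"negative biomass coefficient {k}={v}")


def _rxn(id, stoich, lo, hi, rule="", name="", subsystem=""):
    return Reaction(id=id, name=name or id, stoichiometry=stoich,
                    lower_bound=lo, upper_bound=hi, gene_rule=rule,
                    subsystem=subsystem)


def build_core_model(manifest: FixtureManifest | None = None) -> MetabolicModel:
    """Construct the core glycerol-fermentation model.

    Raw defaults: glycerol exchange open both ways (the growth medium is
    applied by the curation recipe), product exchanges secretion-only,
    formate exchange shipped closed (see module docstring), aerobic GlpD
    and the ATP-dependent DHA kinase present with (0,0) bounds.
    """
    manifest = manifest or FixtureManifest()
    manifest.validate()
    b = manifest.biomass
    delta = manifest.nadh_release

    metabolites = [
        Metabolite(id=f"{m}_c", name=_NAMES[m],
                   formula=ElementalFormula.parse(_FORMULAS[m]), compartment="c")
        for m in _FORMULAS
    ] + [
        Metabolite(id=f"{m}_e", name=_NAMES[m] + " (external)",
                   formula=ElementalFormula.parse(_FORMULAS[m]), compartment="e")
        for m in _EXTERNAL
    ]

    R: list[Reaction] = []

    # glycerol dissimilation routes ------------------------------------
    R.append(_rxn("GLYDH", {"glyc_c": -1, "nad_c": -1, "dha_c": 1, "nadh_c": 1, "h_c": 1},
                  0, INF, "gldA", "glycerol dehydrogenase (GldA)"))
    R.append(_rxn("DHAPT", {"dha_c": -1, "pep_c": -1, "dhap_c": 1, "pyr_c": 1},
                  0, INF, "dhaK", "PEP-dependent DHA kinase (DhaKLM)"))
    R.append(_rxn("DHAK_ATP", {"dha_c": -1, "atp_c": -1, "dhap_c": 1, "adp_c": 1, "h_c": 1},
                  0, 0, "dhaK_cf", "ATP-dependent DHA kinase (CfDhaKL plug-in)"))
    R.append(_rxn("GLPK", {"glyc_c": -1, "atp_c": -1, "g3p_c": 1, "adp_c": 1, "h_c": 1},
                  0, INF, "glpK", "glycerol kinase (GlpK)"))
    R.append(_rxn("G3PD", {"g3p_c": -1, "mqn8_c": -1, "dhap_c": 1, "mql8_c": 1},
                  0, INF, "glpA and glpB and glpC",
                  "anaerobic G3P dehydrogenase (GlpABC)"))
    R.append(_rxn("GLPD", {"g3p_c": -1, "q8_c": -1, "dhap_c": 1, "q8h2_c": 1},
                  0, 0, "glpD", "aerobic G3P dehydrogenase (GlpD; off anaerobically)"))
    R.append(_rxn("G3PD_NADH", {"dhap_c": -1, "nadh_c": -1, "h_c": -1, "g3p_c": 1, "nad_c": 1},
                  0, INF, "gpsA", "NADH-linked G3P dehydrogenase (shuttle arm)"))
    R.append(_rxn("NDH2", {"nadh_c": -1, "h_c": -1, "mqn8_c": -1, "nad_c": 1, "mql8_c": 1},
                  0, INF, "ndh", "NADH:quinone oxidoreductase II"))

    # fructose phosphate bypass and FBP node ---------------------------
    R.append(_rxn("FSA", {"dha_c": -1, "gap_c": -1, "f6p_c": 1},
                  0, INF, "fsaA or fsaB", "fructose 6-phosphate aldolase"))
    R.append(_rxn("PFK", {"f6p_c": -1, "atp_c": -1, "fdp_c": 1, "adp_c": 1, "h_c": 1},
                  0, INF, "pfkA", "phosphofructokinase"))
    R.append(_rxn("FBP", {"fdp_c": -1, "h2o_c": -1, "f6p_c": 1, "pi_c": 1},
                  0, INF, "fbp or glpX or yggF or ybhA", "fructose-1,6-bisphosphatase"))
    R.append(_rxn("FBA", {"fdp_c": -1, "dhap_c": 1, "gap_c": 1},
                  -INF, INF, "fbaA", "fructose-bisphosphate aldolase"))
    R.append(_rxn("TPI", {"dhap_c": -1, "gap_c": 1}, -INF, INF, "tpiA",
                  "triose-phosphate isomerase"))

    # lower glycolysis (GAPDH+PGK and PGM+ENO lumped) -------------------
    R.append(_rxn("GAPD_PGK",
                  {"gap_c": -1, "nad_c": -1, "pi_c": -1, "adp_c": -1,
                   "pg3_c": 1, "atp_c": 1, "nadh_c": 1, "h_c": 1},
                  -INF, INF, "gapA", "GAP dehydrogenase + phosphoglycerate kinase"))
    R.append(_rxn("PGM_ENO", {"pg3_c": -1, "pep_c": 1, "h2o_c": 1},
                  -INF, INF, "eno", "phosphoglycerate mutase + enolase"))

    # PEP node ----------------------------------------------------------
    R.append(_rxn("PYK", {"pep_c": -1, "adp_c": -1, "h_c": -1, "pyr_c": 1, "atp_c": 1},
                  0, INF, "pykA or pykF", "pyruvate kinase"))
    R.append(_rxn("PPS", {"pyr_c": -1, "atp_c": -1, "h2o_c": -1,
                          "pep_c": 1, "amp_c": 1, "pi_c": 1, "h_c": 2},
                  0, INF, "ppsA", "PEP synthetase (2 ATP equivalents)"))
    R.append(_rxn("PPC", {"pep_c": -1, "co2_c": -1, "h2o_c": -1,
                          "oaa_c": 1, "pi_c": 1, "h_c": 1},
                  0, INF, "ppc", "PEP carboxylase"))
    R.append(_rxn("PCK", {"oaa_c": -1, "atp_c": -1, "pep_c": 1, "adp_c": 1, "co2_c": 1},
                  -INF, INF, "pckA", "PEP carboxykinase (reversible)"))
    R.append(_rxn("MDH", {"oaa_c": -1, "nadh_c": -1, "h_c": -1, "mal_c": 1, "nad_c": 1},
                  -INF, INF, "mdh", "malate dehydrogenase"))
    R.append(_rxn("ME1", {"mal_c": -1, "nad_c": -1, "pyr_c": 1, "co2_c": 1, "nadh_c": 1},
                  0, INF, "maeA", "malic enzyme (NAD)"))
    R.append(_rxn("ME2", {"mal_c": -1, "nad_c": -1, "pyr_c": 1, "co2_c": 1, "nadh_c": 1},
                  0, INF, "maeB", "malic enzyme (NADP, carrier lumped)"))

    # succinate branch (electrons lumped through NADH; see module doc) --
    R.append(_rxn("FUM", {"mal_c": -1, "fum_c": 1, "h2o_c": 1}, -INF, INF,
                  "fumB", "fumarase"))
    R.append(_rxn("FRD_NADH", {"fum_c": -1, "nadh_c": -1, "h_c": -1, "succ_c": 1, "nad_c": 1},
                  0, INF, "frdA", "fumarate reductase (electron entry lumped via NADH)"))

    # methylglyoxal / 1,2-PDO branch ------------------------------------
    R.append(_rxn("MGSA", {"dhap_c": -1, "mg_c": 1, "pi_c": 1}, 0, INF,
                  "mgsA", "methylglyoxal synthase"))
    R.append(_rxn("PDO12S", {"mg_c": -1, "nadh_c": -2, "h_c": -2, "pdo12_c": 1, "nad_c": 2},
                  0, INF, "", "methylglyoxal to 1,2-propanediol (2 NADH, lumped)"))

    # fermentative acetyl-CoA block -------------------------------------
    R.append(_rxn("PFL", {"pyr_c": -1, "coa_c": -1, "accoa_c": 1, "for_c": 1},
                  0, INF, "pflB", "pyruvate formate-lyase"))
    R.append(_rxn("PDH", {"pyr_c": -1, "coa_c": -1, "nad_c": -1,
                          "accoa_c": 1, "co2_c": 1, "nadh_c": 1},
                  0, INF, "aceE", "pyruvate dehydrogenase"))
    R.append(_rxn("ADHE", {"accoa_c": -1, "nadh_c": -2, "h_c": -2,
                           "etoh_c": 1, "coa_c": 1, "nad_c": 2},
                  0, INF, "adhE", "aldehyde/alcohol dehydrogenase (AdhE, lumped)"))
    R.append(_rxn("PTAACK", {"accoa_c": -1, "adp_c": -1, "pi_c": -1,
                             "ac_c": 1, "atp_c": 1, "coa_c": 1},
                  0, INF, "pta and ackA", "phosphotransacetylase + acetate kinase"))
    R.append(_rxn("FHL", {"for_c": -1, "h_c": -1, "co2_c": 1, "h2_c": 1},
                  0, INF, "hycE and fdhF", "formate hydrogen-lyase"))
    R.append(_rxn("HYD", {"mql8_c": -1, "mqn8_c": 1, "h2_c": 1},
                  -INF, INF, "hyaB or (hybA and hybC)",
                  "quinone-coupled reversible hydrogenase (HYD1/HYD2)"))

    # truncated TCA branch to α-ketoglutarate ---------------------------
    R.append(_rxn("CS", {"accoa_c": -1, "oaa_c": -1, "h2o_c": -1,
                         "cit_c": 1, "coa_c": 1, "h_c": 1},
                  0, INF, "gltA", "citrate synthase"))
    R.append(_rxn("ACONT", {"cit_c": -1, "icit_c": 1}, -INF, INF, "acnB", "aconitase"))
    R.append(_rxn("ICDH", {"icit_c": -1, "nad_c": -1, "akg_c": 1, "co2_c": 1, "nadh_c": 1},
                  0, INF, "icd", "isocitrate dehydrogenase (carrier lumped)"))

    # energy bookkeeping -------------------------------------------------
    R.append(_rxn("ADK", {"amp_c": -1, "atp_c": -1, "adp_c": 2}, -INF, INF,
                  "adk", "adenylate kinase"))
    R.append(_rxn("ATPM", {"atp_c": -1, "h2o_c": -1, "adp_c": 1, "pi_c": 1, "h_c": 1},
                  0, INF, "", "non-growth-associated ATP maintenance",
                  subsystem="maintenance"))

    # biomass drain -------------------------------------------------------
    gam = b["gam_atp"]
    biomass_stoich = {
        "f6p_c": -b["f6p"], "gap_c": -b["gap"], "pg3_c": -b["pg3"],
        "pep_c": -b["pep"], "pyr_c": -b["pyr"], "oaa_c": -b["oaa"],
        "akg_c": -b["akg"], "accoa_c": -b["accoa"], "for_c": -b["c1_formate"],
        "nh4_c": -b["nh4"], "atp_c": -gam, "h2o_c": -gam, "nad_c": -delta,
        "coa_c": b["accoa"], "adp_c": gam, "pi_c": gam, "h_c": gam,
        "nadh_c": delta,
    }
    R.append(_rxn("BIOMASS", biomass_stoich, 0, INF, "",
                  "biomass drain (precursors + GAM ATP + δ NADH release)",
                  subsystem="biomass"))

    # transport -----------------------------------------------------------
    transports = [
        ("GLYCt", "glyc", 0, INF), ("ETOHt", "etoh", 0, INF), ("ACt", "ac", 0, INF),
        ("SUCCt", "succ", 0, INF), ("FORt", "for", 0, INF), ("CO2t", "co2", -INF, INF),
        ("H2t", "h2", 0, INF), ("PPD12t", "pdo12", 0, INF), ("PIt", "pi", -INF, INF),
        ("NH4t", "nh4", -INF, INF), ("H2Ot", "h2o", -INF, INF), ("Ht", "h", -INF, INF),
    ]
    for tid, m, lo, hi in transports:
        if tid in ("GLYCt", "PIt", "NH4t"):  # uptake direction: e → c
            stoich = {f"{m}_e": -1.0, f"{m}_c": 1.0}
        else:
            stoich = {f"{m}_c": -1.0, f"{m}_e": 1.0}
        R.append(_rxn(tid, stoich, lo, hi, "", f"{_NAMES[m]} transport"))

    # exchanges -------------------------------------------------------------
    exchange_bounds = {
        "glyc": (-INF, INF), "etoh": (0, INF), "ac": (0, INF), "succ": (0, INF),
        "for": (0, 0),  # shipped closed; see module docstring
        "co2": (-INF, INF), "h2": (0, INF), "pdo12": (0, INF),
        "pi": (-INF, INF), "nh4": (-INF, INF), "h2o": (-INF, INF), "h": (-INF, INF),
    }
    for m, (lo, hi) in exchange_bounds.items():
        R.append(_rxn(f"EX_{m}_e", {f"{m}_e": -1.0}, lo, hi, "",
                      f"{_NAMES[m]} exchange", subsystem="exchange"))

    model = MetabolicModel(
        id=manifest.model_id,
        metabolites=metabolites,
        reactions=R,
        objective={"BIOMASS": 1.0},
    )

    if manifest.reaction_count != len(model.reactions):
        raise ValueError(
            f"manifest reaction_count {manifest.reaction_count} != "
            f"constructed {len(model.reactions)}"
        )
    if manifest.metabolite_count != len(model.metabolites):
        raise ValueError(
            f"manifest metabolite_count {manifest.metabolite_count} != "
            f"constructed {len(model.metabolites)}"
        )
    if manifest.gene_count != len(model.genes):
        raise ValueError(
            f"manifest gene_count {manifest.gene_count} != "
            f"constructed {len(model.genes)}"
        )
    return model


def effective_biomass_formula(model: MetabolicModel) -> tuple[ElementalFormula, float]:
    """Net elemental composition removed per unit biomass flux.

    Returns the per-carbon-normalizable net formula of the biomass reaction
    (consumed minus produced over all its metabolites) and the net carbon
    (mmol C per unit biomass), for exact electron-balance audits.
    """
    rxn = model.get_reaction("BIOMASS")
    net: dict[str, float] = {}
    for mid, coeff in rxn.stoichiometry.items():
        formula = model.get_metabolite(mid).formula
        if formula is None:
            raise ValueError(f"biomass metabolite {mid!r} has no formula")
        for element, n in formula.composition.items():
            net[element] = net.get(element, 0.0) - coeff * n
    carbon = net.get("C", 0.0)
    if carbon <= 0:
        raise ValueError("biomass drain removes no net carbon")
    net = {e: v for e, v in net.items() if abs(v) > 1e-9}
    if any(v < 0 for v in net.values()):
        bad = {e: v for e, v in net.items() if v < 0}
        raise ValueError(f"biomass net composition has negative counts: {bad}")
    return ElementalFormula(net), carbon


def augment_with_redox_shuttle(model: MetabolicModel) -> MetabolicModel:
    """Add a reversible NADH→menaquinol transfer plus the NADH-linked G3P
    shuttle arm in its cycle-forming configuration, for futile-cycle
    demonstrations (electrons can then shuttle NADH ↔ quinol in a closed
    loop through the DHAP/G3P pair)."""
    out = model.copy()
    out.reactions.append(
        _rxn("NQR_REV", {"nadh_c": -1, "h_c": -1, "mqn8_c": -1, "nad_c": 1, "mql8_c": 1},
             -INF, INF, "", "reversible NADH:quinone transfer (augmentation)")
    )
    out.log("augment: NQR_REV added (reversible NADH:quinone transfer)")
    return out


# ---------------------------------------------------------------------------
# Toy models
# ---------------------------------------------------------------------------

def build_toy_model(kind: str) -> MetabolicModel:
    """Hand-checkable toys with known optima (stoichiometries documented in
    docs/methods.md):

    - ``single_chain``: source (≤10) → M → sink (≤8); optimum 8.
    - ``branch``: source (≤10) → M; two sinks R1, R2 ≤ 6 each; objective R1
      → 6, with R2 free in [0, 4] at the optimum.
    - ``envelope``: substrate (≤10) split between a biomass sink (yield 1,
      the objective) and a product sink.
    - ``shuttle_cycle``: irreversible pair A→B, B→A plus an exchange: one
      futile-cycle group.
    """
    if kind == "single_chain":
        mets = [Metabolite(id="M")]
        rxns = [
            _rxn("SRC", {"M": 1.0}, 0, 10, subsystem="exchange"),
            _rxn("SNK", {"M": -1.0}, 0, 8, subsystem="exchange"),
        ]
        return MetabolicModel(id="toy_single_chain", metabolites=mets,
                              reactions=rxns, objective={"SNK": 1.0})
    if kind == "branch":
        mets = [Metabolite(id="M")]
        rxns = [
            _rxn("SRC", {"M": 1.0}, 0, 10, subsystem="exchange"),
            _rxn("R1", {"M": -1.0}, 0, 6, subsystem="exchange"),
            _rxn("R2", {"M": -1.0}, 0, 6, subsystem="exchange"),
        ]
        return MetabolicModel(id="toy_branch", metabolites=mets,
                              reactions=rxns, objective={"R1": 1.0})
    if kind == "envelope":
        mets = [Metabolite(id="S")]
        rxns = [
            _rxn("SRC", {"S": 1.0}, 0, 10, subsystem="exchange"),
            _rxn("BIO", {"S": -1.0}, 0, INF, subsystem="exchange"),
            _rxn("PROD", {"S": -1.0}, 0, INF, subsystem="exchange"),
        ]
        return MetabolicModel(id="toy_envelope", metabolites=mets,
                              reactions=rxns, objective={"BIO": 1.0})
    if kind == "shuttle_cycle":
        mets = [Metabolite(id="A"), Metabolite(id="B")]
        rxns = [
            _rxn("EXA", {"A": -1.0}, -5, 5, subsystem="exchange"),
            _rxn("FWD", {"A": -1.0, "B": 1.0}, 0, INF),
            _rxn("REV", {"B": -1.0, "A": 1.0}, 0, INF),
        ]
        return MetabolicModel(id="toy_shuttle_cycle", metabolites=mets,
                              reactions=rxns, objective={"EXA": 1.0})
    raise ValueError(f"unknown toy model kind {kind!r}")


def random_small_model(
    seed: int, n_reactions: int = 6, n_metabolites: int = 4
) -> MetabolicModel:
    """Seeded random sparse model for the LP-vs-vertex-enumeration oracle.

    All bounds are finite (so the flux polytope is bounded and vertex
    enumeration is exhaustive) and straddle zero (so the zero flux vector
    is always feasible).
    """
    if n_reactions > 6 or n_metabolites > 4:
        raise ValueError("random models are capped at 6 reactions / 4 metabolites")
    rng = np.random.default_rng(seed)
    mets = [Metabolite(id=f"m{i}") for i in range(n_metabolites)]
    rxns = []
    for j in range(n_reactions):
        k = int(rng.integers(1, min(3, n_metabolites) + 1))
        chosen = rng.choice(n_metabolites, size=k, replace=False)
        stoich = {f"m{i}": float(rng.choice([-2, -1, 1, 2])) for i in chosen}
        lo = float(rng.choice([0.0, -rng.integers(1, 11)]))
        hi = float(rng.integers(1, 11))
        rxns.append(_rxn(f"r{j}", stoich, lo, hi))
    weights = rng.random(n_reactions).round(3)
    mask = rng.random(n_reactions) < 0.5
    if not mask.any():
        mask[0] = True
    objective = {f"r{j}": float(weights[j]) for j in range(n_reactions) if mask[j]}
    return MetabolicModel(id=f"random_{seed}", metabolites=mets,
                          reactions=rxns, objective=objective)
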