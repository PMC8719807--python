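"""Readers and writers for the JSON model dialect and SBML Level 3 (fbc).

The JSON dialect is the package's primary exchange format and round-trips
exactly (see docs/model_schema.md). SBML support targets Level 3 models
carrying fbc flux bounds and gene-product associations, including published
BiGG genome-scale models; it requires python-libsbml.
"""

from __future__ import annotations

import json
from typing import Optional

from .formula import ElementalFormula
from .model import CouplingConstraint, MetabolicModel, Metabolite, Reaction, Relation


class ModelParseError(ValueError):
    pass


# ---------------------------------------------------------------------------
# JSON dialect
# ---------------------------------------------------------------------------

def model_to_dict(model: MetabolicModel) -> dict:
    return {
        "id": model.id,
        "metabolites": [
            {
                "id": m.id,
                "name": m.name,
                "compartment": m.compartment,
                "formula": dict(m.formula.composition) if m.formula else None,
            }
            for m in model.metabolites
        ],
        "reactions": [
            {
                "id": r.id,
                "name": r.name,
                "stoichiometry": dict(r.stoichiometry),
                "lower_bound": r.lower_bound,
                "upper_bound": r.upper_bound,
                "gene_rule": r.gene_rule,
                "subsystem": r.subsystem,
            }
            for r in model.reactions
        ],
        "objective": dict(model.objective),
        "couplings": [
            {
                "terms": dict(c.terms),
                "relation": c.relation.value,
                "rhs": c.rhs,
                "tag": c.tag,
            }
            for c in model.couplings
        ],
    }


def model_from_dict(data: dict) -> MetabolicModel:
    for key in ("metabolites", "reactions"):
        if key not in data:
            raise ModelParseError(f"model document lacks required key {key!r}")
    metabolites = [
        Metabolite(
            id=m["id"],
            name=m.get("name", ""),
            compartment=m.get("compartment", "c"),
            formula=ElementalFormula(m["formula"]) if m.get("formula") else None,
        )
        for m in data["metabolites"]
    ]
    reactions = [
        Reaction(
            id=r["id"],
            name=r.get("name", ""),
            stoichiometry=r["stoichiometry"],
            lower_bound=float(r.get("lower_bound", 0.0)),
            upper_bound=float(r.get("upper_bound", 1000.0)),
            gene_rule=r.get("gene_rule", ""),
            subsystem=r.get("subsystem", ""),
        )
        for r in data["reactions"]
    ]
    couplings = [
        CouplingConstraint(
            terms=c["terms"],
            relation=Relation(c.get("relation", "EQ")),
            rhs=float(c.get("rhs", 0.0)),
            tag=c.get("tag", ""),
        )
        for c in data.get("couplings", [])
    ]
    return MetabolicModel(
        id=data.get("id", "model"),
        metabolites=metabolites,
        reactions=reactions,
        objective={k: float(v) for k, v in data.get("objective", {}).items()},
        couplings=couplings,
    )


def read_model(path, format: Optional[str] = None) -> MetabolicModel:
    """Read a model from ``path``; format inferred from the suffix
    (``.json`` / ``.xml``/``.sbml``) unless given explicitly."""
    fmt = format or _infer_format(path)
    if fmt == "json":
        with open(path) as fh:
            try:
                data = json.load(fh)
            except json.JSONDecodeError as exc:
                raise ModelParseError(f"{path}: invalid JSON at line {exc.lineno}: {exc.msg}")
        return model_from_dict(data)
    if fmt == "sbml":
        return _read_sbml(path)
    raise ModelParseError(f"unsupported model format {fmt!r}")


def write_model(model: MetabolicModel, path, format: Optional[str] = None) -> None:
    fmt = format or _infer_format(path)
    if fmt == "json":
        with open(path, "w") as fh:
            json.dump(model_to_dict(model), fh, indent=1, sort_keys=False)
            fh.write("\n")
        return
    if fmt == "sbml":
        _write_sbml(model, path)
        return
    raise ModelParseError(f"unsupported model format {fmt!r}")


def _infer_format(path) -> str:
    p = str(path).lower()
    if p.endswith(".json"):
        return "json"
    if p.endswith((".xml", ".sbml")):
        return "sbml"
    raise ModelParseError(f"cannot infer model format from path {path!r}")


# ---------------------------------------------------------------------------
# SBML Level 3 + fbc
# ---------------------------------------------------------------------------

def _require_libsbml():
    try:
        import libsbml  # type: ignore
    except ImportError as exc:  # pragma: no cover
        raise ImportError(
            "SBML support requires python-libsbml; install it or use the "
            "JSON dialect"
        ) from exc
    return libsbml


def _association_to_rule(assoc, label_of) -> str:
    import libsbml

    if assoc is None:
        return ""
    code = assoc.getTypeCode()
    if code == libsbml.SBML_FBC_GENEPRODUCTREF:
        return label_of(assoc.getGeneProduct())
    if code == libsbml.SBML_FBC_AND:
        parts = [_association_to_rule(assoc.getAssociation(i), label_of)
                 for i in range(assoc.getNumAssociations())]
        return "(" + " and ".join(parts) + ")"
    if code == libsbml.SBML_FBC_OR:
        parts = [_association_to_rule(assoc.getAssociation(i), label_of)
                 for i in range(assoc.getNumAssociations())]
        return "(" + " or ".join(parts) + ")"
    raise ModelParseError(f"unsupported gene-association construct {assoc.getElementName()!r}")


def _read_sbml(path) -> MetabolicModel:
    libsbml = _require_libsbml()
    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        err = doc.getError(0)
        raise ModelParseError(
            f"{path}: SBML parse error at line {err.getLine()}: {err.getMessage()}"
        )
    sm = doc.getModel()
    if sm is None:
        raise ModelParseError(f"{path}: document contains no model element")

    gene_label = {}
    mplug = sm.getPlugin("fbc")
    if mplug is not None:
        for i in range(mplug.getNumGeneProducts()):
            gp = mplug.getGeneProduct(i)
            gene_label[gp.getId()] = gp.getLabel() or gp.getId()

    metabolites = []
    for i in range(sm.getNumSpecies()):
        sp = sm.getSpecies(i)
        formula = None
        splug = sp.getPlugin("fbc")
        if splug is not None and splug.isSetChemicalFormula():
            text = splug.getChemicalFormula()
            if text:
                try:
                    formula = ElementalFormula.parse(text)
                except ValueError:
                    formula = None  # elements outside C/H/O/N/P/S (metals etc.)
        metabolites.append(
            Metabolite(id=sp.getId(), name=sp.getName(),
                       compartment=sp.getCompartment() or "c", formula=formula)
        )

    def bound_value(pid: str) -> float:
        param = sm.getParameter(pid)
        if param is None:
            raise ModelParseError(f"flux-bound parameter {pid!r} not found")
        return param.getValue()

    reactions = []
    objective: dict[str, float] = {}
    for i in range(sm.getNumReactions()):
        rx = sm.getReaction(i)
        stoich: dict[str, float] = {}
        for j in range(rx.getNumReactants()):
            ref = rx.getReactant(j)
            stoich[ref.getSpecies()] = stoich.get(ref.getSpecies(), 0.0) - ref.getStoichiometry()
        for j in range(rx.getNumProducts()):
            ref = rx.getProduct(j)
            stoich[ref.getSpecies()] = stoich.get(ref.getSpecies(), 0.0) + ref.getStoichiometry()
        rplug = rx.getPlugin("fbc")
        if rplug is None or not rplug.isSetLowerFluxBound():
            raise ModelParseError(
                f"reaction {rx.getId()!r}: missing fbc flux bounds "
                "(only SBML L3 + fbc models are supported)"
            )
        lb = bound_value(rplug.getLowerFluxBound())
        ub = bound_value(rplug.getUpperFluxBound())
        rule = ""
        gpa = rplug.getGeneProductAssociation()
        if gpa is not None:
            rule = _association_to_rule(gpa.getAssociation(),
                                        lambda gid: gene_label.get(gid, gid))
        reactions.append(
            Reaction(id=rx.getId(), name=rx.getName(), stoichiometry=stoich,
                     lower_bound=lb, upper_bound=ub, gene_rule=rule)
        )

    if mplug is not None and mplug.getNumObjectives() > 0:
        obj = mplug.getActiveObjective() or mplug.getObjective(0)
        sense = 1.0
        if obj.getType() == "minimize":
            sense = -1.0
        for j in range(obj.getNumFluxObjectives()):
            fo = obj.getFluxObjective(j)
            objective[fo.getReaction()] = sense * fo.getCoefficient()

    return MetabolicModel(
        id=sm.getId() or "sbml_model",
        metabolites=metabolites,
        reactions=reactions,
        objective=objective,
    )


def _write_sbml(model: MetabolicModel, path) -> None:
    libsbml = _require_libsbml()
    ns = libsbml.SBMLNamespaces(3, 1)
    ns.addPackageNamespace("fbc", 2)
    doc = libsbml.SBMLDocument(ns)
    doc.setPackageRequired("fbc", False)
    sm = doc.createModel()
    sm.setId(model.id)
    mplug = sm.getPlugin("fbc")
    mplug.setStrict(True)

    compartments = sorted({m.compartment for m in model.metabolites})
    for cid in compartments:
        comp = sm.createCompartment()
        comp.setId(cid)
        comp.setConstant(True)

    for m in model.metabolites:
        sp = sm.createSpecies()
        sp.setId(m.id)
        sp.setName(m.name)
        sp.setCompartment(m.compartment)
        sp.setHasOnlySubstanceUnits(False)
        sp.setBoundaryCondition(False)
        sp.setConstant(False)
        if m.formula is not None and all(
            n == int(n) for n in m.formula.composition.values()
        ):
            sp.getPlugin("fbc").setChemicalFormula(str(m.formula))

    bounds_seen: dict[float, str] = {}

    def bound_param(value: float) -> str:
        if value not in bounds_seen:
            pid = f"fb_{len(bounds_seen)}"
            p = sm.createParameter()
            p.setId(pid)
            p.setValue(value)
            p.setConstant(True)
            bounds_seen[value] = pid
        return bounds_seen[value]

    for r in model.reactions:
        rx = sm.createReaction()
        rx.setId(r.id)
        rx.setName(r.name)
        rx.setReversible(r.lower_bound < 0)
        rx.setFast(False)
        for mid, coeff in r.stoichiometry.items():
            ref = rx.createReactant() if coeff < 0 else rx.createProduct()
            ref.setSpecies(mid)
            ref.setStoichiometry(abs(coeff))
            ref.setConstant(True)
        rplug = rx.getPlugin("fbc")
        rplug.setLowerFluxBound(bound_param(r.lower_bound))
        rplug.setUpperFluxBound(bound_param(r.upper_bound))
        if r.gene_rule.strip():
            gpa = rplug.createGeneProductAssociation()
            # libsbml parses the infix rule and auto-registers gene
            # products with the rule tokens as labels
            gpa.setAssociation(r.gene_rule)

    if model.objective:
        obj = mplug.createObjective()
        obj.setId("obj")
        obj.setType("maximize")
        for rid, w in model.objective.items():
            fo = obj.createFluxObjective()
            fo.setReaction(rid)
            fo.setCoefficient(w)
        mplug.setActiveObjectiveId("obj")

    if model.couplings:
        # SBML fbc has no coupling-constraint construct; keep them in an
        # annotation so a JSON round trip remains the lossless path.
        raise ModelParseError(
            "models with coupling constraints cannot be written to SBML; "
            "use the JSON dialect"
        )

    libsbml.writeSBMLToFile(doc, str(path))
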