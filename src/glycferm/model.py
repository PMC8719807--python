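"""Core data structures for constraint-based metabolic models.

A :class:`MetabolicModel` is the steady-state world ``S·v = 0``: metabolites
(rows), reactions with flux bounds and gene rules (columns), a linear
objective, and optional extra linear coupling constraints (used for yield
fixes and flux-ratio caps). Fluxes are in mmol gCDW⁻¹ h⁻¹; the biomass
reaction's flux is the specific growth rate in h⁻¹.

Sign convention: exchange reactions are written ``metabolite →`` with a
single negative stoichiometric entry, so negative flux is uptake and
positive flux is secretion (BiGG convention).
"""

from __future__ import annotations

import copy
import enum
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import numpy as np

from .formula import ElementalFormula, as_formula


@dataclass
class Metabolite:
    id: str
    name: str = ""
    formula: Optional[ElementalFormula] = None
    compartment: str = "c"

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("metabolite id must be non-empty")
        if not self.compartment:
            raise ValueError(f"metabolite {self.id!r}: compartment must be non-empty")
        if self.formula is not None:
            self.formula = as_formula(self.formula)


@dataclass
class Reaction:
    """A reaction column: signed stoichiometry (negative = consumed), bounds,
    and an optional boolean gene rule (identifiers with AND/OR/parentheses)."""

    id: str
    name: str = ""
    stoichiometry: dict[str, float] = field(default_factory=dict)
    lower_bound: float = 0.0
    upper_bound: float = 1000.0
    gene_rule: str = ""
    subsystem: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("reaction id must be non-empty")
        if not self.stoichiometry:
            raise ValueError(f"reaction {self.id!r}: stoichiometry must be non-empty")
        if self.lower_bound > self.upper_bound:
            raise ValueError(
                f"reaction {self.id!r}: lower bound {self.lower_bound} exceeds "
                f"upper bound {self.upper_bound}"
            )
        self.stoichiometry = {m: float(c) for m, c in self.stoichiometry.items()}

    @property
    def is_exchange(self) -> bool:
        """Exchange/boundary reactions touch exactly one metabolite."""
        return len(self.stoichiometry) == 1

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0 < self.upper_bound


class Relation(str, enum.Enum):
    EQ = "EQ"
    LE = "LE"
    GE = "GE"


@dataclass
class CouplingConstraint:
    """Extra linear constraint ``Σ coeff·v  (=|≤|≥)  rhs`` over reaction fluxes."""

    terms: dict[str, float]
    relation: Relation = Relation.EQ
    rhs: float = 0.0
    tag: str = ""

    def __post_init__(self) -> None:
        if not self.terms:
            raise ValueError("coupling constraint must have at least one term")
        self.relation = Relation(self.relation)
        self.terms = {r: float(c) for r, c in self.terms.items()}


@dataclass
class MediumSpec:
    """Growth-medium boundary conditions.

    ``exchange_bounds`` overwrite exchange reaction bounds (uptake is a
    negative lower bound); ``atpm_flux`` pins the non-growth-associated ATP
    maintenance reaction to a fixed flux.
    """

    exchange_bounds: dict[str, tuple[float, float]] = field(default_factory=dict)
    atpm_flux: float = 0.0
    atpm_reaction: str = "ATPM"

    def __post_init__(self) -> None:
        if self.atpm_flux < 0:
            raise ValueError("atpm_flux must be non-negative")


@dataclass
class Issue:
    code: str
    severity: str  # "error" | "warning"
    subject: str
    message: str


class ValidationReport(list):
    """List of :class:`Issue` records; empty report means the model passes."""

    @property
    def errors(self) -> list[Issue]:
        return [i for i in self if i.severity == "error"]

    @property
    def warnings(self) -> list[Issue]:
        return [i for i in self if i.severity == "warning"]


#: subsystems whose reactions are exempt from elemental-balance checking
BALANCE_EXEMPT_SUBSYSTEMS = {"exchange", "biomass", "maintenance"}


@dataclass
class MetabolicModel:
    id: str = "model"
    metabolites: list[Metabolite] = field(default_factory=list)
    reactions: list[Reaction] = field(default_factory=list)
    objective: dict[str, float] = field(default_factory=dict)
    couplings: list[CouplingConstraint] = field(default_factory=list)
    notes: dict = field(default_factory=dict)

    # -- lookups ---------------------------------------------------------
    def metabolite_index(self) -> dict[str, int]:
        return {m.id: i for i, m in enumerate(self.metabolites)}

    def reaction_index(self) -> dict[str, int]:
        return {r.id: i for i, r in enumerate(self.reactions)}

    def get_reaction(self, rid: str) -> Reaction:
        for r in self.reactions:
            if r.id == rid:
                return r
        raise KeyError(f"unknown reaction id {rid!r}")

    def get_metabolite(self, mid: str) -> Metabolite:
        for m in self.metabolites:
            if m.id == mid:
                return m
        raise KeyError(f"unknown metabolite id {mid!r}")

    def has_reaction(self, rid: str) -> bool:
        return any(r.id == rid for r in self.reactions)

    @property
    def genes(self) -> set[str]:
        """Gene identifiers appearing in any reaction's gene rule."""
        from .generule import rule_genes

        out: set[str] = set()
        for r in self.reactions:
            out |= rule_genes(r.gene_rule)
        return out

    @property
    def exchanges(self) -> list[Reaction]:
        return [r for r in self.reactions if r.is_exchange]

    def copy(self) -> "MetabolicModel":
        return copy.deepcopy(self)

    def log(self, message: str) -> None:
        self.notes.setdefault("log", []).append(message)


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def validate_model(model: MetabolicModel) -> ValidationReport:
    """Structural and elemental validation.

    Reports duplicate ids, dangling references, inverted bounds, orphan
    metabolites and, for fully formula-annotated internal reactions,
    per-element imbalance. Exchange, biomass and maintenance reactions are
    exempt from the balance check. An empty report means the model passes.
    """
    report = ValidationReport()
    met_ids = [m.id for m in model.metabolites]
    rxn_ids = [r.id for r in model.reactions]

    for ids, kind in ((met_ids, "metabolite"), (rxn_ids, "reaction")):
        seen: set[str] = set()
        for i in ids:
            if i in seen:
                report.append(Issue("DUPLICATE_ID", "error", i, f"duplicate {kind} id {i!r}"))
            seen.add(i)

    met_set = set(met_ids)
    rxn_set = set(rxn_ids)
    referenced: set[str] = set()
    for r in model.reactions:
        if r.lower_bound > r.upper_bound:
            report.append(
                Issue("INVERTED_BOUNDS", "error", r.id,
                      f"lower bound {r.lower_bound} > upper bound {r.upper_bound}")
            )
        for mid in r.stoichiometry:
            referenced.add(mid)
            if mid not in met_set:
                report.append(
                    Issue("DANGLING_REFERENCE", "error", r.id,
                          f"reaction {r.id!r} references unknown metabolite {mid!r}")
                )

    for mid in met_ids:
        if mid not in referenced:
            report.append(
                Issue("ORPHAN_METABOLITE", "warning", mid,
                      f"metabolite {mid!r} appears in no reaction")
            )

    for key in model.objective:
        if key not in rxn_set:
            report.append(
                Issue("DANGLING_REFERENCE", "error", key,
                      f"objective references unknown reaction {key!r}")
            )
    for k, c in enumerate(model.couplings):
        for rid in c.terms:
            if rid not in rxn_set:
                report.append(
                    Issue("DANGLING_REFERENCE", "error", rid,
                          f"coupling #{k} references unknown reaction {rid!r}")
                )

    formulas = {m.id: m.formula for m in model.metabolites}
    for r in model.reactions:
        if r.is_exchange or r.subsystem in BALANCE_EXEMPT_SUBSYSTEMS:
            continue
        if any(formulas.get(mid) is None for mid in r.stoichiometry):
            continue  # only fully annotated reactions are checked
        balance: dict[str, float] = {}
        for mid, coeff in r.stoichiometry.items():
            for element, n in formulas[mid].composition.items():
                balance[element] = balance.get(element, 0.0) + coeff * n
        for element, delta in balance.items():
            if abs(delta) > 1e-9:
                report.append(
                    Issue("ELEMENT_IMBALANCE", "error", r.id,
                          f"reaction {r.id!r} unbalanced in {element}: net {delta:+g}")
                )
    return report


def build_stoichiometric_matrix(model: MetabolicModel) -> np.ndarray:
    """Dense stoichiometric matrix S (rows = metabolites, cols = reactions,
    both in model order)."""
    midx = model.metabolite_index()
    S = np.zeros((len(model.metabolites), len(model.reactions)))
    for j, r in enumerate(model.reactions):
        for mid, coeff in r.stoichiometry.items():
            if mid not in midx:
                raise KeyError(
                    f"reaction {r.id!r} references unknown metabolite {mid!r}"
                )
            S[midx[mid], j] = coeff
    return S


def apply_medium(model: MetabolicModel, medium: MediumSpec) -> MetabolicModel:
    """Return a copy with exchange bounds overwritten and ATPM fixed.

    Every exchange id in the medium must exist in the model. Electron
    acceptor exchanges are closed by listing them in ``exchange_bounds``
    with a zero lower bound.
    """
    out = model.copy()
    ridx = {r.id: r for r in out.reactions}
    for rid, (lo, hi) in medium.exchange_bounds.items():
        if rid not in ridx:
            raise KeyError(f"medium references unknown exchange reaction {rid!r}")
        rxn = ridx[rid]
        if not rxn.is_exchange:
            raise ValueError(f"medium entry {rid!r} is not an exchange reaction")
        rxn.lower_bound, rxn.upper_bound = float(lo), float(hi)
        out.log(f"medium: {rid} bounds set to ({lo}, {hi})")
    if medium.atpm_reaction:
        if medium.atpm_reaction not in ridx:
            raise KeyError(
                f"medium references unknown ATPM reaction {medium.atpm_reaction!r}"
            )
        atpm = ridx[medium.atpm_reaction]
        atpm.lower_bound = atpm.upper_bound = float(medium.atpm_flux)
        out.log(f"medium: {medium.atpm_reaction} fixed at {medium.atpm_flux}")
    return out
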