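"""Degree-of-reduction bookkeeping and electron-balance audits.

The degree of reduction per carbon, κ, counts the electrons a compound can
donate on full oxidation to CO₂, H₂O and NH₃, per carbon atom, using the
standard elemental valences C=+4, H=+1, O=−2, N=−3 (ammonia reference),
P=+5, S=+6. Glycerol (C₃H₈O₃) has κ = 14/3 ≈ 4.67, above the average
biomass value of 4.3 (CH₁.₉O₀.₅N₀.₂), which is why cell synthesis from
glycerol nets out reducing equivalents that fermentation must re-absorb.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

from .formula import ElementalFormula, as_formula
from .lp import FluxSolution
from .model import MetabolicModel

#: electrons contributed per atom on full oxidation (NH₃ reference for N)
DEFAULT_VALENCES: dict[str, float] = {"C": 4, "H": 1, "O": -2, "N": -3, "P": 5, "S": 6}


@dataclass
class RedoxSpec:
    valences: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_VALENCES))


def electron_content(
    formula, valences: Optional[Mapping[str, float]] = None
) -> float:
    """Total available electrons per molecule: Σ valence(e)·count(e).

    Defined for carbon-free species too — H₂ → 2, CO₂ → 0, formate
    (CH₂O₂) → 2.
    """
    f = as_formula(formula)
    v = valences or DEFAULT_VALENCES
    return sum(v[e] * n for e, n in f.composition.items())


def degree_of_reduction(
    formula, valences: Optional[Mapping[str, float]] = None
) -> float:
    """κ, electrons per carbon. Rejects carbon-free formulas (use
    :func:`electron_content` for those)."""
    f = as_formula(formula)
    n_carbon = f.count("C")
    if n_carbon <= 0:
        raise ValueError(
            f"degree of reduction undefined for carbon-free formula {f}; "
            "use electron_content instead"
        )
    return electron_content(f, valences) / n_carbon


@dataclass
class AuditRow:
    species: str
    flux: float
    electrons_per_unit: float
    electron_flux: float


@dataclass
class ElectronAudit:
    rows: list[AuditRow]
    biomass_electron_flux: float
    residual: float

    def to_tsv(self, path) -> None:
        import pandas as pd

        df = pd.DataFrame(
            [(r.species, r.flux, r.electrons_per_unit, r.electron_flux) for r in self.rows]
            + [("biomass", float("nan"), float("nan"), self.biomass_electron_flux),
               ("residual", float("nan"), float("nan"), self.residual)],
            columns=["species", "flux", "electrons_per_unit", "electron_flux"],
        )
        df.to_csv(path, sep="\t", index=False)


def audit_electron_balance(
    model: MetabolicModel,
    solution: FluxSolution,
    biomass_formula,
    biomass_carbon_flux: float,
    valences: Optional[Mapping[str, float]] = None,
) -> ElectronAudit:
    """Electron-flux ledger of a flux solution.

    Sums electron content × flux over every exchange reaction (secretion
    positive, uptake negative) and adds the biomass electron drain,
    computed as κ(biomass) × biomass carbon flux. For an elementally
    balanced model the residual of a feasible solution is numerically zero;
    tests assert |residual| ≤ 1e−6·|glycerol uptake electron flux|.
    """
    bio = as_formula(biomass_formula)
    rows: list[AuditRow] = []
    total = 0.0
    for rxn in model.exchanges:
        (mid, coeff), = rxn.stoichiometry.items()
        met = model.get_metabolite(mid)
        if met.formula is None:
            raise ValueError(
                f"exchanged metabolite {mid!r} carries no formula; "
                "electron audit requires formulas on all exchanged species"
            )
        flux = solution.fluxes.get(rxn.id, 0.0)
        # exchange is written "met →" with coeff −1: positive flux removes
        # the species from the system
        removal = -coeff * flux
        e_per = electron_content(met.formula, valences)
        e_flux = e_per * removal
        rows.append(AuditRow(mid, flux, e_per, e_flux))
        total += e_flux
    kappa = degree_of_reduction(bio, valences)
    biomass_e = kappa * biomass_carbon_flux
    residual = total + biomass_e
    return ElectronAudit(rows=rows, biomass_electron_flux=biomass_e, residual=residual)
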