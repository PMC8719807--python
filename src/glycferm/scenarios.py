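"""Named analysis scenarios and gene-level knockout simulation.

A scenario is a base curation recipe plus optional extra edits and a set
of gene deletions. Pathway-level removals (e.g. taking out GlpK-GlpABC or
the fructose-phosphate bypass) are expressed as reaction removals in
``extra_edits``; enzyme-level deletions go through gene–protein–reaction
rules, so isozyme redundancy (pykA/pykF, fsaA/fsaB, the four FBPases,
HYD1/HYD2) behaves as it does in deletion strains.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import yaml

from .curation import CurationRecipe, RecipeStep, apply_recipe, _apply_step
from .generule import evaluate_gene_rule
from .lp import FluxSolution, SolverStatus, solve_fba
from .model import MetabolicModel

#: exchange reactions whose fluxes are reported for every scenario
DEFAULT_PRODUCT_EXCHANGES = (
    "EX_etoh_e", "EX_h2_e", "EX_for_e", "EX_ac_e", "EX_succ_e", "EX_pdo12_e",
)


@dataclass
class ScenarioSpec:
    name: str
    base_recipe: Optional[CurationRecipe] = None
    gene_deletions: set[str] = field(default_factory=set)
    extra_edits: list[RecipeStep] = field(default_factory=list)
    description: str = ""


@dataclass
class KnockoutResult:
    scenario: str
    deleted_genes: set[str]
    disabled_reactions: list[str]
    status: SolverStatus
    growth_rate: float
    product_fluxes: dict[str, float]
    solution: Optional[FluxSolution] = None


def delete_genes(
    model: MetabolicModel, genes: Sequence[str]
) -> tuple[MetabolicModel, list[str]]:
    """Disable every reaction whose gene rule evaluates inactive with the
    given genes deleted. Unknown genes warn rather than error, so a genome-
    wide deletion list can be screened against a reduced model."""
    genes = set(genes)
    unknown = genes - model.genes
    if unknown:
        warnings.warn(
            f"genes not in model, ignored: {sorted(unknown)}", stacklevel=2
        )
    out = model.copy()
    disabled: list[str] = []
    for r in out.reactions:
        if r.gene_rule.strip() and not evaluate_gene_rule(r.gene_rule, genes):
            r.lower_bound = r.upper_bound = 0.0
            disabled.append(r.id)
    if genes:
        out.log(f"delete_genes: {sorted(genes)} -> disabled {disabled}")
    return out, disabled


def build_scenario_model(model: MetabolicModel, scenario: ScenarioSpec) -> MetabolicModel:
    """Base recipe, then extra edits, then gene deletions."""
    out = model
    if scenario.base_recipe is not None:
        out = apply_recipe(out, scenario.base_recipe)
    recipe = scenario.base_recipe or CurationRecipe(name="inline")
    for step in scenario.extra_edits:
        out = _apply_step(out, recipe, step)
        out.log(f"scenario[{scenario.name}] edit {step.op}: {step.args}")
    out, _ = delete_genes(out, scenario.gene_deletions)
    return out


def run_scenario(
    model: MetabolicModel,
    scenario: ScenarioSpec,
    product_exchanges: Sequence[str] = DEFAULT_PRODUCT_EXCHANGES,
) -> KnockoutResult:
    """Apply a scenario and solve FBA.

    INFEASIBLE is reported as growth 0 with the status preserved: with the
    fixed acetate/succinate yield couplings and ATP maintenance, an
    infeasible program is the model's way of saying "no growth under the
    imposed yields".
    """
    edited = build_scenario_model(model, scenario)
    _, disabled = delete_genes(model, scenario.gene_deletions)
    sol = solve_fba(edited)
    if sol.status is SolverStatus.OPTIMAL:
        growth = sol.objective_value
        products = {rid: sol.fluxes.get(rid, 0.0) for rid in product_exchanges}
    else:
        growth = 0.0
        products = {rid: 0.0 for rid in product_exchanges}
    return KnockoutResult(
        scenario=scenario.name,
        deleted_genes=set(scenario.gene_deletions),
        disabled_reactions=disabled,
        status=sol.status,
        growth_rate=growth,
        product_fluxes=products,
        solution=sol,
    )


def knockout_matrix(
    model: MetabolicModel,
    scenarios: Sequence[ScenarioSpec],
    product_exchanges: Sequence[str] = DEFAULT_PRODUCT_EXCHANGES,
):
    """One row per scenario: growth rate, status, product fluxes
    (TSV-exportable pandas DataFrame)."""
    import pandas as pd

    rows = []
    for sc in scenarios:
        res = run_scenario(model, sc, product_exchanges)
        row = {
            "scenario": res.scenario,
            "deleted_genes": ",".join(sorted(res.deleted_genes)),
            "status": res.status.value,
            "growth_rate": res.growth_rate,
        }
        row.update(res.product_fluxes)
        rows.append(row)
    columns = ["scenario", "deleted_genes", "status", "growth_rate",
               *product_exchanges]
    return pd.DataFrame(rows, columns=columns)


# ---------------------------------------------------------------------------
# Registry files
# ---------------------------------------------------------------------------

def load_scenarios(path, recipes: dict[str, CurationRecipe]) -> dict[str, ScenarioSpec]:
    """Load a YAML scenario registry.

    Format: ``scenarios:`` list of entries with ``name``, ``recipe`` (key
    into ``recipes``), optional ``gene_deletions``, optional ``extra_edits``
    (recipe-step mappings) and ``description``.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    out: dict[str, ScenarioSpec] = {}
    for entry in raw.get("scenarios", []):
        name = entry["name"]
        if name in out:
            raise ValueError(f"duplicate scenario name {name!r}")
        recipe_key = entry.get("recipe")
        if recipe_key is not None and recipe_key not in recipes:
            raise ValueError(f"scenario {name!r}: unknown recipe {recipe_key!r}")
        out[name] = ScenarioSpec(
            name=name,
            base_recipe=recipes[recipe_key] if recipe_key else None,
            gene_deletions=set(entry.get("gene_deletions", [])),
            extra_edits=[
                RecipeStep(op=s["op"], args={k: v for k, v in s.items() if k != "op"})
                for s in entry.get("extra_edits", [])
            ],
            description=entry.get("description", ""),
        )
    return out
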