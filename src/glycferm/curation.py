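"""Model curation as declarative, logged edit operations.

The curation recipe captures the edits that turn a raw anaerobic model into
the analysis base case: fixing observed product yields (acetate, succinate)
as molar-yield couplings against glycerol uptake, removing NAD(P)H→quinone
electron transfer reactions and futile shuttle cycles, capping the
fructose-phosphate bypass relative to glycerol transport, and plain bound
edits. Recipes are YAML files whose steps name abstract *roles* resolved to
model-specific reaction ids through an ``id_map``, so the same recipe text
applies to the shipped core model or to a genome-scale model with BiGG ids.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import yaml

from .model import CouplingConstraint, MediumSpec, MetabolicModel, Relation, apply_medium


class CurationError(ValueError):
    pass


@dataclass
class RecipeStep:
    op: str  # FIX_YIELD | REMOVE_REACTIONS | CAP_RATIO | CLOSE_EXCHANGES | SET_BOUNDS | APPLY_MEDIUM
    args: dict = field(default_factory=dict)


@dataclass
class CurationRecipe:
    name: str
    steps: list[RecipeStep] = field(default_factory=list)
    id_map: dict[str, str] = field(default_factory=dict)
    medium: Optional[MediumSpec] = None

    def resolve(self, role_or_id: str) -> str:
        return self.id_map.get(role_or_id, role_or_id)

    def resolve_list(self, items: Iterable[str]) -> list[str]:
        return [self.resolve(x) for x in items]


def load_recipe(path) -> CurationRecipe:
    """Load a YAML recipe: ``name``, ``id_map``, optional ``medium``
    (exchange_bounds + atpm_flux) and a ``steps`` list."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict) or "steps" not in raw:
        raise CurationError(f"recipe {path}: missing 'steps' key")
    medium = None
    if "medium" in raw and raw["medium"] is not None:
        m = raw["medium"]
        medium = MediumSpec(
            exchange_bounds={k: (float(v[0]), float(v[1]))
                             for k, v in m.get("exchange_bounds", {}).items()},
            atpm_flux=float(m.get("atpm_flux", 0.0)),
            atpm_reaction=m.get("atpm_reaction", "ATPM"),
        )
    steps = [RecipeStep(op=s["op"], args={k: v for k, v in s.items() if k != "op"})
             for s in raw["steps"]]
    return CurationRecipe(
        name=raw.get("name", "recipe"),
        steps=steps,
        id_map=dict(raw.get("id_map", {})),
        medium=medium,
    )


# ---------------------------------------------------------------------------
# Edit operations (each returns an edited copy and logs what it did)
# ---------------------------------------------------------------------------

def fix_product_yield(
    model: MetabolicModel,
    product_exchange: str,
    substrate_exchange: str,
    yield_mol_per_mol: float,
    equality: bool = True,
) -> MetabolicModel:
    """Constrain product secretion to a molar yield on substrate uptake.

    With the uptake sign convention (substrate flux negative), the coupling
    is  v_product + yield·v_substrate = 0, i.e. product = yield·|uptake|.
    ``equality=False`` encodes ≤ instead (product at most the yield).
    """
    if yield_mol_per_mol < 0:
        raise CurationError("yield must be non-negative")
    for rid in (product_exchange, substrate_exchange):
        if not model.has_reaction(rid):
            raise CurationError(f"fix_product_yield: unknown exchange {rid!r}")
    out = model.copy()
    tag = f"yield:{product_exchange}:{substrate_exchange}"
    _guard_duplicate(out, tag)
    out.couplings.append(
        CouplingConstraint(
            terms={product_exchange: 1.0, substrate_exchange: yield_mol_per_mol},
            relation=Relation.EQ if equality else Relation.LE,
            rhs=0.0,
            tag=tag,
        )
    )
    out.log(
        f"fix_product_yield: {product_exchange} = {yield_mol_per_mol} mol/mol "
        f"of |{substrate_exchange}| ({'=' if equality else '<='})"
    )
    return out


def remove_reactions(model: MetabolicModel, ids: Sequence[str], reason: str = "") -> MetabolicModel:
    """Delete the listed reactions (metabolites are never deleted; orphans
    are reported by validate_model as warnings). Unknown ids are an error —
    no silent skips."""
    missing = [rid for rid in ids if not model.has_reaction(rid)]
    if missing:
        raise CurationError(f"remove_reactions: unknown reaction ids {missing}")
    out = model.copy()
    drop = set(ids)
    out.reactions = [r for r in out.reactions if r.id not in drop]
    out.objective = {k: v for k, v in out.objective.items() if k not in drop}
    out.couplings = [c for c in out.couplings if not (set(c.terms) & drop)]
    for rid in ids:
        out.log(f"remove_reaction: {rid} ({reason})")
    return out


def cap_flux_ratio(
    model: MetabolicModel,
    capped_reaction: str,
    reference_reaction: str,
    fraction: float,
) -> MetabolicModel:
    """Cap a reaction's flux at ``fraction`` of the magnitude of a reference
    uptake flux: with the reference an uptake exchange (negative flux), the
    constraint is  v_capped + fraction·v_reference ≤ 0."""
    if not (0 < fraction <= 1):
        raise CurationError("fraction must be in (0, 1]")
    for rid in (capped_reaction, reference_reaction):
        if not model.has_reaction(rid):
            raise CurationError(f"cap_flux_ratio: unknown reaction {rid!r}")
    out = model.copy()
    tag = f"cap:{capped_reaction}:{reference_reaction}"
    _guard_duplicate(out, tag)
    out.couplings.append(
        CouplingConstraint(
            terms={capped_reaction: 1.0, reference_reaction: fraction},
            relation=Relation.LE,
            rhs=0.0,
            tag=tag,
        )
    )
    out.log(f"cap_flux_ratio: {capped_reaction} <= {fraction} * |{reference_reaction}|")
    return out


def set_bounds(model: MetabolicModel, reaction: str, lo: float, hi: float,
               reason: str = "") -> MetabolicModel:
    if not model.has_reaction(reaction):
        raise CurationError(f"set_bounds: unknown reaction {reaction!r}")
    if lo > hi:
        raise CurationError(f"set_bounds: inverted bounds ({lo}, {hi})")
    out = model.copy()
    rxn = out.get_reaction(reaction)
    rxn.lower_bound, rxn.upper_bound = float(lo), float(hi)
    out.log(f"set_bounds: {reaction} -> ({lo}, {hi}) ({reason})")
    return out


def close_exchanges(model: MetabolicModel, ids: Sequence[str]) -> MetabolicModel:
    """Set the listed exchange reactions to (0, 0)."""
    out = model
    for rid in ids:
        out = set_bounds(out, rid, 0.0, 0.0, reason="exchange closed")
    return out


def _guard_duplicate(model: MetabolicModel, tag: str) -> None:
    if any(c.tag == tag for c in model.couplings):
        raise CurationError(
            f"constraint {tag!r} already present; applying the same recipe "
            "twice is rejected"
        )


# ---------------------------------------------------------------------------
# Futile-cycle detection (advisory)
# ---------------------------------------------------------------------------

def detect_futile_cycles(model: MetabolicModel, tolerance: float = 1e-6) -> list[set[str]]:
    """Find internal loops able to carry flux with every exchange closed.

    All exchange reactions are closed, the objective is dropped, and FVA is
    run over the internal reactions: any reaction with a nonzero feasible
    range participates in a stoichiometrically balanced internal cycle.
    Flagged reactions are grouped by shared metabolites. Advisory only —
    removal remains an explicit recipe step.
    """
    from .lp import LPBackend, SolverStatus

    probe = model.copy()
    for r in probe.reactions:
        if r.is_exchange:
            r.lower_bound = r.upper_bound = 0.0
        else:
            # forced fluxes (e.g. fixed ATP maintenance) are relaxed toward
            # zero so the closed system admits the zero vector; direction
            # information is kept
            r.lower_bound = min(r.lower_bound, 0.0)
            r.upper_bound = max(r.upper_bound, 0.0)
    backend = LPBackend()
    # min/max each internal reaction with a zero objective
    from .lp import _build_program  # internal reuse; same LP world

    prog = _build_program(probe)
    import numpy as np

    flagged: list[str] = []
    n = len(prog.rxn_ids)
    for r in probe.reactions:
        if r.is_exchange:
            continue
        j = prog.index[r.id]
        e = np.zeros(n)
        e[j] = 1.0
        lo_s, lo, _ = backend.solve(e, prog.A_eq, prog.b_eq, prog.A_ub, prog.b_ub, prog.bounds)
        hi_s, hi, _ = backend.solve(-e, prog.A_eq, prog.b_eq, prog.A_ub, prog.b_ub, prog.bounds)
        if lo_s is not SolverStatus.OPTIMAL or hi_s is not SolverStatus.OPTIMAL:
            raise CurationError(f"futile-cycle probe failed on {r.id!r}: {lo_s}/{hi_s}")
        if max(abs(lo), abs(hi)) > tolerance:
            flagged.append(r.id)

    # group flagged reactions that share a metabolite (union-find)
    parent = {rid: rid for rid in flagged}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a: str, b: str) -> None:
        parent[find(a)] = find(b)

    by_met: dict[str, list[str]] = {}
    for rid in flagged:
        for mid in model.get_reaction(rid).stoichiometry:
            by_met.setdefault(mid, []).append(rid)
    for members in by_met.values():
        for other in members[1:]:
            union(members[0], other)
    groups: dict[str, set[str]] = {}
    for rid in flagged:
        groups.setdefault(find(rid), set()).add(rid)
    return sorted(groups.values(), key=lambda g: sorted(g)[0])


# ---------------------------------------------------------------------------
# Recipe application
# ---------------------------------------------------------------------------

def apply_recipe(model: MetabolicModel, recipe: CurationRecipe) -> MetabolicModel:
    """Apply recipe steps in order, logging one structured line per step.

    The first failing step aborts with its index and reason; the input
    model is never mutated.
    """
    out = model.copy()
    out.log(f"recipe: {recipe.name}")
    if recipe.medium is not None:
        medium = MediumSpec(
            exchange_bounds={recipe.resolve(k): v
                             for k, v in recipe.medium.exchange_bounds.items()},
            atpm_flux=recipe.medium.atpm_flux,
            atpm_reaction=recipe.resolve(recipe.medium.atpm_reaction),
        )
        out = apply_medium(out, medium)
    for i, step in enumerate(recipe.steps):
        try:
            out = _apply_step(out, recipe, step)
        except Exception as exc:
            raise CurationError(
                f"recipe {recipe.name!r} failed at step {i} ({step.op}): {exc}"
            ) from exc
        out.log(f"step[{i}] {step.op}: {step.args}")
    return out


def _apply_step(model: MetabolicModel, recipe: CurationRecipe, step: RecipeStep) -> MetabolicModel:
    a = step.args
    if step.op == "FIX_YIELD":
        return fix_product_yield(
            model,
            recipe.resolve(a["product_exchange"]),
            recipe.resolve(a["substrate_exchange"]),
            float(a["yield"]),
            equality=bool(a.get("equality", True)),
        )
    if step.op == "REMOVE_REACTIONS":
        return remove_reactions(model, recipe.resolve_list(a["ids"]), a.get("reason", ""))
    if step.op == "CAP_RATIO":
        return cap_flux_ratio(
            model,
            recipe.resolve(a["capped_reaction"]),
            recipe.resolve(a["reference_reaction"]),
            float(a["fraction"]),
        )
    if step.op == "CLOSE_EXCHANGES":
        return close_exchanges(model, recipe.resolve_list(a["ids"]))
    if step.op == "SET_BOUNDS":
        return set_bounds(model, recipe.resolve(a["reaction"]),
                          float(a["lo"]), float(a["hi"]), a.get("reason", ""))
    raise CurationError(f"unknown recipe op {step.op!r}")
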