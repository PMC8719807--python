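"""Access to the shipped recipes, scenario registry and core model file."""

from __future__ import annotations

from importlib import resources

from .curation import CurationRecipe, load_recipe
from .model import MetabolicModel
from .scenarios import ScenarioSpec, load_scenarios


def _data_path(name: str):
    return resources.files("glycferm.data") / name


def core_recipe() -> CurationRecipe:
    """The shipped base-case recipe for the core model."""
    with resources.as_file(_data_path("recipe_base_core.yaml")) as p:
        return load_recipe(p)


def ijo1366_recipe() -> CurationRecipe:
    """The shipped base-case recipe in BiGG identifiers (full-scale runs)."""
    with resources.as_file(_data_path("recipe_base_ijo1366.yaml")) as p:
        return load_recipe(p)


def core_scenarios() -> dict[str, ScenarioSpec]:
    """The shipped scenario registry bound to the core base recipe."""
    recipes = {"base": core_recipe()}
    with resources.as_file(_data_path("scenarios_core.yaml")) as p:
        return load_scenarios(p, recipes)


def shipped_core_model() -> MetabolicModel:
    """The checked-in JSON copy of the core model (regenerated by
    scripts/regenerate_core_model.py; tests assert it matches the code)."""
    from .io import read_model

    with resources.as_file(_data_path("core_model.json")) as p:
        return read_model(p, "json")
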