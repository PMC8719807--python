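"""Curation recipe operations: yield fixes, removals, ratio caps, cycles."""

import pytest

from glycferm.curation import (
    CurationError,
    apply_recipe,
    cap_flux_ratio,
    detect_futile_cycles,
    fix_product_yield,
    remove_reactions,
)
from glycferm.fixtures import augment_with_redox_shuttle, build_toy_model
from glycferm.lp import SolverStatus, solve_fba, solve_fva
from glycferm.registry import core_recipe


class TestFixProductYield:
    @pytest.mark.parametrize("y,expected", [(0.012, 0.24), (0.015, 0.30), (0.0, 0.0)])
    def test_yield_arithmetic_at_fixed_uptake(self, h2_model, y, expected):
        """With uptake fixed at -20, yield y forces product flux 20*y."""
        m = h2_model.copy()
        m.couplings = []  # start from clean slate for this check
        m.get_reaction("EX_glyc_e").lower_bound = -20.0
        m.get_reaction("EX_glyc_e").upper_bound = -20.0
        m = fix_product_yield(m, "EX_pdo12_e", "EX_glyc_e", y)
        sol = solve_fba(m)
        assert sol.status is SolverStatus.OPTIMAL
        assert sol.fluxes["EX_pdo12_e"] == pytest.approx(expected, abs=1e-6)

    def test_yields_hold_in_optimal_solutions(self, h2_model, pdo_model):
        for model in (h2_model, pdo_model):
            sol = solve_fba(model)
            uptake = abs(sol.fluxes["EX_glyc_e"])
            assert sol.fluxes["EX_ac_e"] == pytest.approx(0.012 * uptake, abs=1e-6)
            assert sol.fluxes["EX_succ_e"] == pytest.approx(0.015 * uptake, abs=1e-6)

    def test_unknown_exchange_rejected(self, core_model):
        with pytest.raises(CurationError, match="EX_ghost"):
            fix_product_yield(core_model, "EX_ghost", "EX_glyc_e", 0.01)


class TestRemoveReactions:
    def test_removed_hydrogenase_carries_no_flux(self, core_model, h2_model):
        m = remove_reactions(h2_model, ["HYD"], "scenario")
        assert not m.has_reaction("HYD")
        sol = solve_fba(m)
        assert sol.status is SolverStatus.OPTIMAL  # 1,2-PDO mode takes over

    def test_empty_list_is_identity(self, core_model):
        m = remove_reactions(core_model, [], "")
        assert [r.id for r in m.reactions] == [r.id for r in core_model.reactions]

    def test_unknown_id_rejected_not_skipped(self, core_model):
        with pytest.raises(CurationError, match="NOPE"):
            remove_reactions(core_model, ["GLYDH", "NOPE"], "")

    def test_metabolites_survive_as_orphans(self, core_model):
        from glycferm.model import validate_model

        m = remove_reactions(core_model, ["MGSA", "PDO12S", "PPD12t", "EX_pdo12_e"], "")
        report = validate_model(m)
        assert any(i.code == "ORPHAN_METABOLITE" and i.subject == "mg_c"
                   for i in report)
        assert not report.errors


class TestCapFluxRatio:
    def test_cap_limits_bypass_to_fraction_of_uptake(self, h2_model):
        m = cap_flux_ratio(h2_model, "FSA", "EX_glyc_e", 0.20)
        fva = solve_fva(m, 1.0, ["FSA", "EX_glyc_e"])
        lo_u, hi_u = fva.ranges["EX_glyc_e"]
        assert hi_u == pytest.approx(-20.0, abs=1e-6)  # uptake pinned at optimum
        # the bypass is otherwise favourable, so its FVA max sits exactly
        # on the cap: 0.2 * 20 = 4
        assert fva.ranges["FSA"][1] == pytest.approx(4.0, abs=1e-6)

    def test_full_fraction_cap_never_binds(self, h2_model):
        capped = cap_flux_ratio(h2_model, "FSA", "EX_glyc_e", 1.0)
        assert solve_fba(capped).objective_value == pytest.approx(
            solve_fba(h2_model).objective_value, abs=1e-8
        )

    def test_fraction_range_enforced(self, h2_model):
        with pytest.raises(CurationError):
            cap_flux_ratio(h2_model, "FSA", "EX_glyc_e", 0.0)


class TestDetectFutileCycles:
    def test_irreversible_pair_is_one_group(self):
        groups = detect_futile_cycles(build_toy_model("shuttle_cycle"))
        assert groups == [{"FWD", "REV"}]

    def test_acyclic_chain_has_no_cycles(self):
        assert detect_futile_cycles(build_toy_model("single_chain")) == []

    def test_curated_fixture_has_no_cycles(self, h2_model):
        assert detect_futile_cycles(h2_model) == []

    def test_redox_shuttle_augmentation_flagged_then_removable(self, core_model):
        """A reversible NADH:quinone transfer plus the G3P shuttle lets
        electrons cycle NADH <-> menaquinol; removal of the transfer
        reactions bounds the loop again."""
        augmented = augment_with_redox_shuttle(core_model)
        groups = detect_futile_cycles(augmented)
        flagged = set().union(*groups) if groups else set()
        assert {"NQR_REV", "G3PD_NADH", "G3PD"} <= flagged
        cleaned = remove_reactions(augmented, ["NQR_REV", "G3PD_NADH"], "curation")
        carriers = {"nadh_c", "mql8_c"}
        for group in detect_futile_cycles(cleaned):
            touched = set()
            for rid in group:
                touched |= set(cleaned.get_reaction(rid).stoichiometry)
            assert not carriers <= touched


class TestApplyRecipe:
    def test_base_recipe_supports_growth(self, core_model):
        curated = apply_recipe(core_model, core_recipe())
        sol = solve_fba(curated)
        assert sol.status is SolverStatus.OPTIMAL
        assert sol.objective_value > 0

    def test_recipe_is_logged(self, core_model):
        curated = apply_recipe(core_model, core_recipe())
        log = curated.notes["log"]
        assert any("FIX_YIELD" in line for line in log)
        assert any("REMOVE_REACTIONS" in line for line in log)

    def test_applying_twice_rejected_on_duplicate_constraint(self, core_model):
        recipe = core_recipe()
        once = apply_recipe(core_model, recipe)
        with pytest.raises(CurationError, match="already present"):
            apply_recipe(once, recipe)

    def test_unknown_role_aborts_with_step_index(self, core_model):
        recipe = core_recipe()
        recipe.id_map["acetate_exchange"] = "EX_missing"
        with pytest.raises(CurationError, match=r"step 0"):
            apply_recipe(core_model, recipe)
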