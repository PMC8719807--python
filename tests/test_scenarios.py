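"""Knockout scenarios: gene deletions, the pathway-removal matrix, and the
stoichiometric couplings the curated network must express."""

import pytest

from glycferm.lp import SolverStatus, is_growth_coupled, solve_fba, solve_fva
from glycferm.scenarios import delete_genes, knockout_matrix, run_scenario


def growth(core_model, scenarios, name):
    return run_scenario(core_model, scenarios[name]).growth_rate


class TestDeleteGenes:
    def test_single_gene_disables_its_reaction(self, core_model):
        m, disabled = delete_genes(core_model, {"dhaK"})
        rxn = m.get_reaction("DHAPT")
        assert (rxn.lower_bound, rxn.upper_bound) == (0.0, 0.0)
        assert "DHAPT" in disabled

    def test_isozyme_pair_requires_double_deletion(self, core_model):
        m, disabled = delete_genes(core_model, {"pykA"})
        assert "PYK" not in disabled
        m, disabled = delete_genes(core_model, {"pykA", "pykF"})
        assert "PYK" in disabled

    def test_empty_set_is_identity(self, core_model):
        m, disabled = delete_genes(core_model, set())
        assert disabled == []
        assert [(r.lower_bound, r.upper_bound) for r in m.reactions] == [
            (r.lower_bound, r.upper_bound) for r in core_model.reactions
        ]

    def test_unknown_gene_warns_not_errors(self, core_model):
        with pytest.warns(UserWarning, match="notAGene"):
            delete_genes(core_model, {"notAGene"})

    @pytest.mark.parametrize("genes", [{"gldA"}, {"adhE"}, {"pykA", "pykF"}])
    def test_deletion_never_raises_optimum(self, h2_model, genes):
        base = solve_fba(h2_model).objective_value
        m, _ = delete_genes(h2_model, genes)
        sol = solve_fba(m)
        mu = sol.objective_value if sol.status is SolverStatus.OPTIMAL else 0.0
        assert mu <= base + 1e-7


class TestPathwayMatrix:
    def test_pep_node_matrix_ordering(self, core_model, scenarios):
        """Removing PEP-decoupled dissimilation routes hurts growth; adding
        the PEP-synthetase deletion on top abolishes it."""
        base = growth(core_model, scenarios, "fig5b_base")
        no_pyk = growth(core_model, scenarios, "fig5b_no_pyk")
        no_dec = growth(core_model, scenarios, "fig5b_no_decoupled")
        no_dec_no_pps = growth(core_model, scenarios, "fig5b_no_decoupled_no_pps")
        assert base >= no_pyk >= no_dec > 0.0
        assert no_dec_no_pps == 0.0

    def test_pyk_removal_has_no_further_effect_without_decoupled_routes(
        self, core_model, scenarios
    ):
        no_dec = growth(core_model, scenarios, "fig5b_no_decoupled")
        no_dec_no_pyk = growth(core_model, scenarios, "fig5b_no_decoupled_no_pyk")
        assert no_dec_no_pyk == pytest.approx(no_dec, rel=1e-6)

    def test_atp_dependent_kinase_rescues_pps_deletion(self, core_model, scenarios):
        """A PEP-independent (ATP-dependent) DHA kinase restores growth in
        the no-decoupled, PEP-synthetase-deleted background."""
        dead = run_scenario(core_model, scenarios["fig5b_no_decoupled_no_pps"])
        rescued = run_scenario(core_model,
                               scenarios["fig5b_no_decoupled_no_pps_atpdhak"])
        assert dead.growth_rate == 0.0
        assert rescued.status is SolverStatus.OPTIMAL
        assert rescued.growth_rate > 1e-6

    def test_infeasible_reported_as_zero_growth_with_status(self, core_model, scenarios):
        res = run_scenario(core_model, scenarios["fig5b_no_decoupled_no_pps"])
        assert res.status is SolverStatus.INFEASIBLE
        assert res.growth_rate == 0.0


class TestKnockoutMatrix:
    def test_one_row_per_scenario_with_products(self, core_model, scenarios):
        chosen = [scenarios[n] for n in
                  ("keio_gldA", "keio_glpK", "keio_ppc", "keio_hycE")]
        df = knockout_matrix(core_model, chosen)
        assert len(df) == 4
        assert {"growth_rate", "status", "EX_etoh_e", "EX_h2_e"} <= set(df.columns)

    def test_empty_scenario_list_gives_empty_table(self, core_model):
        df = knockout_matrix(core_model, [])
        assert len(df) == 0

    def test_all_genes_deleted_abolishes_growth(self, core_model, scenarios):
        from glycferm.scenarios import ScenarioSpec

        sc = ScenarioSpec(name="everything",
                          base_recipe=scenarios["h2_mode"].base_recipe,
                          gene_deletions=set(core_model.genes))
        with pytest.warns(UserWarning):  # some genes vanish with curation removals
            res = run_scenario(core_model, sc)
        assert res.growth_rate == 0.0


class TestEssentialityPatterns:
    """Deletion phenotypes of the dissimilation routes on the refined
    (bypass-capped) scenarios."""

    def test_gldA_essential_in_pdo_mode(self, core_model, scenarios):
        assert growth(core_model, scenarios, "keio_gldA") == 0.0

    def test_dhaK_essential_under_both_modes(self, core_model, scenarios):
        base = growth(core_model, scenarios, "h2_mode_capped")
        h2_dhak = growth(core_model, scenarios, "keio_dhaK")
        assert h2_dhak < 0.25 * base
        from glycferm.scenarios import ScenarioSpec

        pdo_sc = scenarios["pdo_mode_capped"]
        dhak_pdo = ScenarioSpec(name="pdo_dhak", base_recipe=pdo_sc.base_recipe,
                                extra_edits=pdo_sc.extra_edits,
                                gene_deletions={"dhaK"})
        assert run_scenario(core_model, dhak_pdo).growth_rate == 0.0

    def test_adhE_essential_under_both_modes(self, core_model, scenarios):
        base = growth(core_model, scenarios, "h2_mode_capped")
        assert growth(core_model, scenarios, "keio_adhE") < 0.1 * base

    def test_no_dissimilation_route_no_growth(self, core_model, scenarios):
        from glycferm.scenarios import ScenarioSpec

        sc = ScenarioSpec(name="no_routes",
                          base_recipe=scenarios["h2_mode"].base_recipe,
                          gene_deletions={"gldA", "glpK"})
        assert run_scenario(core_model, sc).growth_rate == 0.0


class TestRedoxModeCouplings:
    def test_ethanol_and_h2_growth_coupled_in_h2_mode(self, h2_model):
        assert is_growth_coupled(h2_model, "EX_etoh_e")
        assert is_growth_coupled(h2_model, "EX_h2_e")
        assert not is_growth_coupled(h2_model, "EX_pdo12_e")

    def test_pdo_growth_coupled_only_without_reversible_hydrogenase(self, pdo_model):
        assert is_growth_coupled(pdo_model, "EX_pdo12_e")

    def test_h2_mode_outgrows_pdo_mode(self, h2_model, pdo_model):
        assert solve_fba(h2_model).objective_value >= \
            solve_fba(pdo_model).objective_value - 1e-9

    def test_glpabc_flux_equals_hydrogenase_flux(self, h2_model):
        """Menaquinol is produced only by GlpABC and consumed only by the
        reversible hydrogenase, so their optimal fluxes coincide."""
        fva = solve_fva(h2_model, 1.0, ["G3PD", "HYD"])
        g_lo, g_hi = fva.ranges["G3PD"]
        h_lo, h_hi = fva.ranges["HYD"]
        assert g_lo == pytest.approx(h_lo, abs=1e-6)
        assert g_hi == pytest.approx(h_hi, abs=1e-6)
        assert g_hi - g_lo < 1e-6  # pinned at the optimum

    def test_pdo_mode_h2_stoichiometric_with_ethanol_plus_acetate(self, pdo_model):
        """Without the reversible hydrogenase, H2 arises solely from
        formate splitting, i.e. one H2 per acetyl unit secreted."""
        sol = solve_fba(pdo_model)
        assert sol.fluxes["EX_h2_e"] == pytest.approx(
            sol.fluxes["EX_etoh_e"] + sol.fluxes["EX_ac_e"], abs=1e-6
        )

    def test_dissimilation_variability_at_optimum(self, h2_model):
        """Product fluxes are pinned while the GldA-DhaKLM and FP-bypass
        routes can trade flux against each other."""
        fva = solve_fva(h2_model, 1.0, ["EX_etoh_e", "FSA", "DHAPT"])
        etoh_lo, etoh_hi = fva.ranges["EX_etoh_e"]
        assert etoh_hi - etoh_lo < 1e-6
        assert fva.ranges["FSA"][1] - fva.ranges["FSA"][0] > 1.0
        assert fva.ranges["DHAPT"][1] - fva.ranges["DHAPT"][0] > 1.0

    def test_pep_coupling_of_dha_kinase(self, h2_model):
        """Every mole of DHA phosphorylated consumes one PEP and releases
        one pyruvate (the cycle-forming coupling), and the route is active
        at the optimum."""
        rxn = h2_model.get_reaction("DHAPT")
        assert rxn.stoichiometry["pep_c"] == -1.0
        assert rxn.stoichiometry["pyr_c"] == 1.0
        assert solve_fba(h2_model).fluxes["DHAPT"] > 1.0


class TestRegistry:
    def test_shipped_registry_loads_and_names_are_unique(self, scenarios):
        assert {"h2_mode", "pdo_mode", "fp_capped"} <= set(scenarios)
        keio = [n for n in scenarios if n.startswith("keio_")]
        assert len(keio) >= 25
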