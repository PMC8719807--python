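"""Model data structures, validation, matrix construction and medium."""

import numpy as np
import pytest

from glycferm.model import (
    MediumSpec,
    MetabolicModel,
    Metabolite,
    Reaction,
    apply_medium,
    build_stoichiometric_matrix,
    validate_model,
)


def mini_model(**overrides):
    mets = [
        Metabolite(id="A", formula="C6H12O6"),
        Metabolite(id="B", formula="C3H6O3"),
    ]
    rxns = [
        Reaction(id="EX_A", stoichiometry={"A": -1.0}, lower_bound=-10,
                 upper_bound=0, subsystem="exchange"),
        Reaction(id="SPLIT", stoichiometry={"A": -1.0, "B": 2.0}, upper_bound=10),
        Reaction(id="EX_B", stoichiometry={"B": -1.0}, upper_bound=20,
                 subsystem="exchange"),
    ]
    model = MetabolicModel(id="mini", metabolites=mets, reactions=rxns,
                           objective={"EX_B": 1.0})
    for k, v in overrides.items():
        setattr(model, k, v)
    return model


class TestValidation:
    def test_clean_model_gives_empty_report(self):
        assert validate_model(mini_model()) == []

    def test_core_fixture_is_clean(self, core_model):
        assert validate_model(core_model) == []

    def test_orphan_metabolite_is_warned(self):
        m = mini_model()
        m.metabolites.append(Metabolite(id="lonely"))
        report = validate_model(m)
        assert [i.code for i in report] == ["ORPHAN_METABOLITE"]
        assert report.warnings and not report.errors

    def test_element_imbalance_is_an_error(self):
        # A (C6) -> B (C3) loses three carbons
        m = mini_model()
        m.reactions[1] = Reaction(id="SPLIT", stoichiometry={"A": -1.0, "B": 1.0},
                                  upper_bound=10)
        codes = [i.code for i in validate_model(m)]
        assert "ELEMENT_IMBALANCE" in codes

    def test_duplicate_and_dangling_are_errors(self):
        m = mini_model()
        m.metabolites.append(Metabolite(id="A"))
        m.reactions[1].stoichiometry["ghost"] = 1.0
        codes = {i.code for i in validate_model(m)}
        assert {"DUPLICATE_ID", "DANGLING_REFERENCE"} <= codes

    def test_exchange_and_biomass_exempt_from_balance(self, core_model):
        # biomass drain is not elementally closed but must not be flagged
        report = validate_model(core_model)
        assert not any(i.subject == "BIOMASS" for i in report)


class TestStoichiometricMatrix:
    def test_conversion_column(self):
        S = build_stoichiometric_matrix(mini_model())
        # SPLIT column: -1 at row A, +2 at row B
        assert S[:, 1].tolist() == [-1.0, 2.0]

    def test_exchange_column_single_entry(self):
        S = build_stoichiometric_matrix(mini_model())
        assert S[:, 0].tolist() == [-1.0, 0.0]
        assert np.count_nonzero(S[:, 0]) == 1

    def test_fixture_shape_matches_manifest(self, core_model):
        from glycferm.fixtures import FixtureManifest

        S = build_stoichiometric_matrix(core_model)
        manifest = FixtureManifest()
        assert S.shape == (manifest.metabolite_count, manifest.reaction_count)

    def test_internal_columns_elementally_balanced(self, core_model):
        """For every internal formula-complete reaction, sum of coeff *
        element-count is zero for C, H, O, N (and P, S)."""
        formulas = {m.id: m.formula for m in core_model.metabolites}
        for r in core_model.reactions:
            if r.is_exchange or r.subsystem in ("biomass", "maintenance"):
                continue
            for element in "CHONPS":
                net = sum(coeff * formulas[mid].count(element)
                          for mid, coeff in r.stoichiometry.items())
                assert abs(net) < 1e-9, (r.id, element, net)


class TestApplyMedium:
    def test_glycerol_uptake_and_atpm_pinned(self, core_model):
        medium = MediumSpec(exchange_bounds={"EX_glyc_e": (-20.0, 0.0)},
                            atpm_flux=3.15)
        m = apply_medium(core_model, medium)
        glyc = m.get_reaction("EX_glyc_e")
        atpm = m.get_reaction("ATPM")
        assert (glyc.lower_bound, glyc.upper_bound) == (-20.0, 0.0)
        assert (atpm.lower_bound, atpm.upper_bound) == (3.15, 3.15)
        # original untouched
        assert core_model.get_reaction("EX_glyc_e").lower_bound == -1000.0

    def test_electron_acceptor_exchange_closed_to_uptake(self):
        m = mini_model()
        m.metabolites.append(Metabolite(id="o2"))
        m.reactions.append(Reaction(id="EX_o2", stoichiometry={"o2": -1.0},
                                    lower_bound=-1000, upper_bound=1000,
                                    subsystem="exchange"))
        m.reactions.append(Reaction(id="RESP", stoichiometry={"o2": -1.0, "B": -1.0,
                                                              "A": 1.0}))
        out = apply_medium(m, MediumSpec(exchange_bounds={"EX_o2": (0.0, 1000.0)},
                                         atpm_reaction=""))
        assert out.get_reaction("EX_o2").lower_bound == 0.0

    def test_unknown_exchange_rejected(self, core_model):
        with pytest.raises(KeyError, match="EX_nope"):
            apply_medium(core_model, MediumSpec(exchange_bounds={"EX_nope": (0, 0)}))

    def test_non_exchange_target_rejected(self, core_model):
        with pytest.raises(ValueError, match="not an exchange"):
            apply_medium(core_model,
                         MediumSpec(exchange_bounds={"PYK": (0, 0)},
                                    atpm_reaction=""))


class TestInvariants:
    def test_reaction_rejects_inverted_bounds(self):
        with pytest.raises(ValueError, match="lower bound"):
            Reaction(id="r", stoichiometry={"A": 1.0}, lower_bound=5, upper_bound=1)

    def test_reaction_rejects_empty_stoichiometry(self):
        with pytest.raises(ValueError, match="non-empty"):
            Reaction(id="r", stoichiometry={})
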