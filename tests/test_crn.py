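"""Model compilation: species, reactions, conservation, serialization."""

import numpy as np
import pytest
from lxml import etree

from fflnoise import (
    ParameterSet,
    build_model,
    conservation_laws,
    export_model,
    full_catalog,
    get_entry,
    import_model,
    propensities,
    stoichiometry,
)
from fflnoise.crn import monomial_matrix

SAMPLED_MODELS = [
    "c1-OR", "c1-AND", "c4-OR", "i2-AND", "chain-2",
    "c1c1-minp-OR", "c1i4-minp-uOR-lAND", "c1i4-mint-OR", "i2i2-mint-AND",
]


class TestSpeciesStructure:
    def test_one_step_c1_or_species(self, c1_or):
        assert c1_or.species_names == ["S", "X_i", "X_a", "Y_i", "Y_a", "Z_i", "Z_a"]

    def test_two_step_adds_intermediate_forms(self):
        crn = build_model("c1-OR", "two-step")
        assert "X_m" in crn.species_names and "Z_m" in crn.species_names
        assert crn.n_species == 10

    def test_coupled_node_sets(self):
        crn = build_model("c1c1-minp-OR")
        assert crn.protein_nodes == ["X1", "X2", "Y", "Z"]
        crn = build_model("c1i4-mint-OR")
        assert crn.protein_nodes == ["X", "Y1", "Y2", "Z"]

    def test_unknown_scheme_rejected(self):
        with pytest.raises(ValueError):
            build_model("c1-OR", "three-step")


class TestConservation:
    @pytest.mark.parametrize("model_id", SAMPLED_MODELS)
    @pytest.mark.parametrize("scheme", ["one-step", "two-step"])
    def test_pool_indicators_annihilate_stoichiometry(self, model_id, scheme):
        crn = build_model(model_id, scheme)
        S = stoichiometry(crn)
        names = crn.species_names
        laws = conservation_laws(crn)
        assert len(laws) == len(crn.protein_nodes)
        for forms, total in laws:
            assert total == 60.0
            v = np.zeros(len(names))
            for f in forms:
                v[names.index(f)] = 1.0
            assert np.all(v @ S == 0)
            assert "S" not in forms

    def test_minp_has_four_pools(self):
        assert len(conservation_laws(build_model("c1c1-minp-OR"))) == 4


class TestPropensities:
    def test_stoichiometry_column_of_activation(self, c1_or):
        S = stoichiometry(c1_or)
        j = [r.name for r in c1_or.reactions].index("X_act0_by_S")
        col = S[:, j]
        assert col[c1_or.species_index("X_i")] == -1
        assert col[c1_or.species_index("X_a")] == 1
        assert np.abs(col).sum() == 2

    def test_input_driven_activation_rate(self, c1_or):
        # kp/s_ref * S * X_i = (10/6)*6*50 = 500
        x = np.zeros(c1_or.n_species)
        x[c1_or.species_index("S")] = 6
        x[c1_or.species_index("X_i")] = 50
        a = propensities(c1_or, x)
        j = [r.name for r in c1_or.reactions].index("X_act0_by_S")
        assert a[j] == pytest.approx(500.0)

    def test_constitutive_inactivation_rate(self, c1_or):
        x = np.zeros(c1_or.n_species)
        x[c1_or.species_index("X_a")] = 12
        a = propensities(c1_or, x)
        j = [r.name for r in c1_or.reactions].index("X_deact0")
        assert a[j] == pytest.approx(60.0)

    def test_and_gate_rate_constant_halved_and_normalized(self):
        crn = build_model("c1-AND")
        rxn = next(r for r in crn.reactions if r.name == "Z_act0_AND")
        assert set(rxn.modifiers) == {"X_a", "Y_a"}
        assert rxn.rate == pytest.approx(0.5 * 10.0 / 60.0 / 60.0)

    def test_negative_state_rejected(self, c1_or):
        with pytest.raises(ValueError):
            propensities(c1_or, -np.ones(c1_or.n_species))

    def test_propensity_monomials_are_multilinear(self):
        for model_id in SAMPLED_MODELS:
            E = monomial_matrix(build_model(model_id))
            assert E.max() <= 1

    def test_nonnegative_propensities_at_random_states(self, rng):
        crn = build_model("c1i4-minp-uOR-lAND")
        for _ in range(20):
            x = rng.integers(0, 60, size=crn.n_species).astype(float)
            assert (propensities(crn, x) >= 0).all()


class TestParameterSet:
    def test_defaults(self, params):
        assert (params.k1, params.k2, params.k3) == (1.0, 1.0, 1.0)
        assert (params.kp, params.kpp, params.ka) == (10.0, 40.0, 5.0)
        assert params.total == 60.0 and params.and_factor == 0.5

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            ParameterSet(kp=0.0)


class TestSerialization:
    @pytest.mark.parametrize("model_id", ["c1-OR", "c1i4-minp-uOR-lAND"])
    def test_json_round_trip_identity(self, model_id):
        crn = build_model(model_id)
        doc = export_model(crn, "json")
        assert import_model(doc) == crn

    def test_export_is_deterministic(self):
        a = export_model(build_model("c1i4-mint-OR"), "json")
        b = export_model(build_model(get_entry("c1i4-mint-OR")), "json")
        assert a == b

    def test_sbml_well_formed_with_expected_species(self, c1_or):
        doc = export_model(c1_or, "sbml")
        root = etree.fromstring(doc.encode())
        ns = {"s": "http://www.sbml.org/sbml/level3/version2/core"}
        species = root.findall(".//s:listOfSpecies/s:species", ns)
        assert len(species) == 7
        reactions = root.findall(".//s:listOfReactions/s:reaction", ns)
        assert len(reactions) == len(c1_or.reactions)

    def test_unknown_format_rejected(self, c1_or):
        with pytest.raises(ValueError):
            export_model(c1_or, "copasi")


def test_every_catalog_model_compiles_under_both_schemes():
    for entry in full_catalog():
        for scheme in ("one-step", "two-step"):
            crn = build_model(entry, scheme)
            assert crn.n_reactions > 3
            assert conservation_laws(crn)
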