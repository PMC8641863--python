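"""Motif enumeration: sign algebra, gate admissibility, catalog counts."""

import json

import pytest
from hypothesis import given, strategies as st

from fflnoise import (
    classify_ffl,
    enumerate_chains,
    enumerate_isolated,
    enumerate_mint,
    enumerate_minp,
    full_catalog,
    gate_options,
    get_entry,
)
from fflnoise.catalog import (
    FFL_TABLE,
    export_catalog_jsonl,
    exclusion_list_rule,
    model_id_for,
    register_drop_rule,
    sign_product,
    _minp_topology,
    _mint_topology,
)

signs = st.sampled_from(["+", "-"])


class TestSignAlgebra:
    def test_product_rules(self):
        assert sign_product("+", "+") == "+"
        assert sign_product("+", "-") == "-"
        assert sign_product("-", "-") == "+"

    @given(signs, signs, signs)
    def test_coherence_iff_sign_product_matches(self, a, b, c):
        label = classify_ffl(a, b, c)
        assert label.startswith("c") == (sign_product(a, b) == c)

    def test_classification_is_a_bijection(self):
        labels = {
            classify_ffl(a, b, c)
            for a in "+-" for b in "+-" for c in "+-"
        }
        assert labels == {"c1", "c2", "c3", "c4", "i1", "i2", "i3", "i4"}

    def test_anchored_types(self):
        # all-activating; doubly-inhibitory long arm; inhibited intermediate
        assert classify_ffl("+", "+", "+") == "c1"
        assert classify_ffl("-", "-", "+") == "c4"
        assert classify_ffl("-", "+", "+") == "i4"

    def test_invalid_sign_rejected(self):
        with pytest.raises(ValueError):
            classify_ffl("+", "0", "+")


class TestGateOptions:
    @pytest.mark.parametrize(
        "inputs, expected",
        [
            (["+", "+"], ["AND", "OR"]),
            (["-", "-"], ["AND", "OR"]),
            (["+", "-"], ["OR"]),
            (["+", "+", "+"], ["AND", "OR"]),
            (["+", "+", "-"], ["OR"]),
        ],
    )
    def test_same_sign_admits_both_gates(self, inputs, expected):
        assert gate_options(inputs) == expected

    def test_single_regulator_has_no_gate(self):
        with pytest.raises(ValueError):
            gate_options(["+"])


class TestCatalogCounts:
    def test_isolated_has_12_gated_models(self):
        entries = enumerate_isolated()
        assert len(entries) == 12
        assert {e.model_id for e in entries} == {
            "c1-AND", "c1-OR", "c2-OR", "c3-AND", "c3-OR", "c4-OR",
            "i1-OR", "i2-AND", "i2-OR", "i3-OR", "i4-AND", "i4-OR",
        }

    def test_chains_have_4_models_and_no_gates(self):
        entries = enumerate_chains()
        assert len(entries) == 4
        assert all(e.gates == {} for e in entries)
        chain1 = next(e for e in entries if e.model_id == "chain-1")
        assert all(s == "+" for _, _, s in chain1.topology.edges)

    def test_mint_has_26_models_over_20_topologies(self):
        entries = enumerate_mint()
        assert len(entries) == 26
        assert len({e.topology.edges for e in entries}) == 20

    def test_minp_naive_rule_gives_42_over_20_topologies(self):
        entries = enumerate_minp("none")
        assert len(entries) == 42
        assert len({e.topology.edges for e in entries}) == 20

    def test_unknown_drop_rule_rejected(self):
        with pytest.raises(ValueError, match="unknown drop rule"):
            enumerate_minp("no-such-rule")

    def test_registered_exclusion_list_is_applied(self):
        register_drop_rule(
            "_test_drop", exclusion_list_rule(["c1c1-minp-AND", "c1c1-minp-OR"])
        )
        entries = enumerate_minp("_test_drop")
        assert len(entries) == 40
        assert "c1c1-minp-OR" not in {e.model_id for e in entries}

    def test_no_duplicate_model_ids_in_full_catalog(self):
        ids = [e.model_id for e in full_catalog()]
        assert len(ids) == len(set(ids)) == 84

    def test_gate_variant_counts_follow_z_input_signs(self):
        # coherent types with equal-sign Z inputs get two variants,
        # mixed-sign Z inputs exactly one
        by_type = {}
        for e in enumerate_isolated():
            by_type.setdefault(e.topology.branch_types[0], []).append(e)
        for label, (s_xy, s_yz, s_xz) in FFL_TABLE.items():
            expected = 2 if s_yz == s_xz else 1
            assert len(by_type[label]) == expected


class TestCanonicalization:
    @given(signs, signs, signs, signs, signs)
    def test_branch_swap_yields_identical_topology(self, u1, l1, u2, l2, shared):
        a, b = (u1, l1), (u2, l2)
        assert _minp_topology(a, b, shared) == _minp_topology(b, a, shared)
        assert _mint_topology(a, b, shared) == _mint_topology(b, a, shared)

    def test_branch_labels_sorted_coherent_first(self):
        ids = {e.model_id for e in full_catalog()}
        assert "c4i1-minp-OR" in ids
        assert "c1i4-mint-OR" in ids
        assert "i1c4-minp-OR" not in ids


class TestLabelsAndExport:
    def test_field_style_labels(self):
        assert get_entry("c1-OR").model_id == "c1-OR"
        e = get_entry("c1c1-minp-uAND-lOR")
        assert e.gates == {"Y": "AND", "Z": "OR"}
        assert model_id_for(e.topology, e.gates) == "c1c1-minp-uAND-lOR"

    def test_unknown_model_id(self):
        with pytest.raises(KeyError):
            get_entry("c9-XOR")

    def test_jsonl_export_round_trips_and_is_stable(self):
        entries = enumerate_chains()
        text = export_catalog_jsonl(entries)
        assert text == export_catalog_jsonl(entries)
        lines = text.splitlines()
        assert len(lines) == 4
        doc = json.loads(lines[0])
        assert doc["family"] == "chain"
        assert ["S", "X", "+"] in doc["edges"]
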