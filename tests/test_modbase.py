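"""Modified-base parameter files, the extended alphabet, and corrections."""

import json

import pytest

from modfold import (AlphabetError, ModFileError, ModelSettings,
                     build_constraints, builtin_sets, encode_sequence,
                     load_builtin, parse_mod_json, trnadb_aliases)

MINIMAL = {
    "modified_base": {
        "name": "Test mod",
        "one_letter_code": "X",
        "unmodified": "A",
        "fallback": "A",
        "pairing_partners": ["U"],
        "stacking_energies": {"XAUU": -1.5},
    }
}


class TestParseModJson:
    def test_minimal_document_round_trips(self):
        s = parse_mod_json(json.dumps(MINIMAL))
        assert s.one_letter_code == "X"
        assert len(s.stacking) == 1
        assert s.stacking["XAUU"].dG37 == -1.5
        assert s.stacking["XAUU"].dH is None

    @pytest.mark.parametrize("missing", [
        "one_letter_code", "unmodified", "fallback", "pairing_partners", "name"])
    def test_missing_mandatory_key_rejected(self, missing):
        doc = {"modified_base": dict(MINIMAL["modified_base"])}
        del doc["modified_base"][missing]
        with pytest.raises(ModFileError, match=missing):
            parse_mod_json(doc)

    def test_canonical_letter_code_rejected(self):
        doc = {"modified_base": dict(MINIMAL["modified_base"],
                                     one_letter_code="A")}
        with pytest.raises(ModFileError):
            parse_mod_json(doc)

    def test_bad_context_key_named_in_error(self):
        doc = {"modified_base": dict(MINIMAL["modified_base"],
                                     stacking_energies={"XX": -1})}
        with pytest.raises(ModFileError, match="XX"):
            parse_mod_json(doc)

    def test_orphan_enthalpy_rejected(self):
        doc = {"modified_base": dict(MINIMAL["modified_base"],
                                     stacking_enthalpies={"AXUU": -9.0})}
        with pytest.raises(ModFileError):
            parse_mod_json(doc)

    def test_unknown_keys_warn_but_parse(self):
        doc = {"modified_base": dict(MINIMAL["modified_base"], frobnicate=1)}
        with pytest.warns(UserWarning, match="frobnicate"):
            parse_mod_json(doc)

    def test_invalid_json_text_rejected(self):
        with pytest.raises(ModFileError):
            parse_mod_json("{not json")


class TestBuiltins:
    def test_six_sets_with_documented_pairing_rules(self):
        sets = {s.name.split()[0].lower(): s for s in builtin_sets()}
        assert len(sets) == 6
        psi = load_builtin("pseudouridine")
        assert psi.unmodified == "U" and psi.pairing_partners == {"A"}
        ino = load_builtin("inosine")
        assert ino.pairing_partners == {"U", "C"} and ino.fallback == "G"
        assert load_builtin("nebularine").pairing_partners == {"U"}
        assert load_builtin("m6A").one_letter_code == "6"
        assert load_builtin("dihydrouridine").fallback == "U"
        assert load_builtin("7DA").unmodified == "A"

    def test_pseudouridine_stacking_matches_literature_table(self):
        psi = load_builtin("P")
        assert psi.stacking["GPCA"].dG37 == pytest.approx(-3.29)
        assert psi.stacking["APUA"].dG37 == pytest.approx(-2.8)
        assert psi.stacking["APUA"].dH == pytest.approx(-22.08)
        assert psi.terminal["PA"].dG37 == pytest.approx(0.31)

    def test_m1a_is_not_an_energy_set(self):
        with pytest.raises(KeyError, match="alias"):
            load_builtin("m1A")
        aliases = trnadb_aliases()
        assert aliases['"']["unpaired"] is True
        assert aliases["R"]["unpaired"] is True
        assert aliases["T"]["fallback"] == "U"


class TestEncodeSequence:
    def test_plain_rna_passes_through(self):
        ms = encode_sequence("ACGU", ())
        assert ms.proxy == "ACGU" and not ms.mods

    def test_fallback_substitution_and_mod_registry(self):
        ms = encode_sequence("APGU", [load_builtin("P")])
        assert ms.proxy == "AUGU"
        assert set(ms.mods) == {1}
        assert ms.mods[1].one_letter_code == "P"

    def test_inosine_uses_its_fallback_not_its_unmodified_base(self):
        ms = encode_sequence("AIGU", [load_builtin("I")])
        assert ms.proxy == "AGGU"

    def test_unresolvable_character_names_position(self):
        with pytest.raises(AlphabetError, match="position 2"):
            encode_sequence("AXGU", ())

    def test_alias_precedence_over_parameter_sets(self):
        # tRNA-database '7' (7-methylguanosine -> G) wins over the 7DA set
        ms = encode_sequence("A7GU", [load_builtin("7")], trnadb_aliases())
        assert ms.proxy == "AGGU" and not ms.mods

    def test_decode_round_trip(self):
        raw = 'GC"PDT?GC'
        ms = encode_sequence(raw, builtin_sets(), trnadb_aliases())
        assert ms.decode() == raw
        assert len(ms.raw) == len(ms.proxy)


class TestBuildConstraints:
    def test_stack_correction_is_tabulated_minus_proxy(self, tables, settings):
        """Helix 5'-GP-3'/3'-CA-5': the face correction equals the literature
        GPCA stacking value minus the Turner G.C-over-U.A proxy stack."""
        ms = encode_sequence("GGPAAAAAAACC", [load_builtin("P")])
        _, soft = build_constraints(ms, settings, tables)
        # pairs (1,10) G.C and (2,9) P.A delimit the corrected stack
        tab = int(100.0 * -3.29)           # GPCA, truncated to the 0.01 grid
        proxy = int(tables.stack[2, 5])    # stack[GC][AU] = -2.20
        assert soft.faces["stack"][(1, 10)] == tab - proxy == -109

    def test_wobble_adjacent_stack_has_no_entry_hence_zero(self, tables, settings):
        # P stacked on a G.U wobble pair: no tabulated value -> no face
        ms = encode_sequence("GGPAAAAAAAUC", [load_builtin("P")])
        # stack context (1,10): pair G.U wobble below P.A
        _, soft = build_constraints(ms, settings, tables)
        assert soft.faces["stack"].get((1, 10), 0) == 0

    def test_empty_partner_set_forces_unpaired(self, tables, settings):
        doc = {"modified_base": {
            "name": "blocker", "one_letter_code": "Z", "unmodified": "A",
            "fallback": "A", "pairing_partners": []}}
        s = parse_mod_json(doc)
        ms = encode_sequence("GGZAAAAACC", [s])
        hard, _ = build_constraints(ms, settings, tables)
        assert 2 in hard.unpaired_only

    def test_sum_of_differences_for_two_distinct_modifications(self, tables, settings):
        """A stack face joining two distinct modified bases carries the sum
        of each base's individual difference to the unmodified case."""
        psi, dhu = load_builtin("P"), load_builtin("D")
        both = encode_sequence("GPDAAAAAAAAC", [psi, dhu])
        only_p = encode_sequence("GPUAAAAAAAAC", [psi])
        only_d = encode_sequence("GUDAAAAAAAAC", [dhu])
        key = None
        _, soft_b = build_constraints(both, settings, tables)
        _, soft_p = build_constraints(only_p, settings, tables)
        _, soft_d = build_constraints(only_d, settings, tables)
        for k in soft_b.faces["stack"]:
            assert soft_b.faces["stack"][k] == (
                soft_p.faces["stack"].get(k, 0) + soft_d.faces["stack"].get(k, 0))
        assert soft_b.faces["stack"]  # at least one such face exists
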