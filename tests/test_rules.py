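"""Rule engine: residue hierarchy, enzymatic cascades, Met excision."""

import pytest
import yaml

from ndegron.rules import (
    AMBIGUITY_CODES,
    CANONICAL_RESIDUES,
    OXIDIZED_CYS,
    EnzymaticStep,
    RecogninSite,
    ResidueClass,
    RuleTable,
    RuleTableError,
    apply_met_excision,
    cascade_path,
    classify_residue,
)

DESTABILIZING = set("RKHFWYLIDENQC")
STABILIZING = set("AGMPSTV")


class TestPartition:
    def test_all_twenty_canonical_residues_assigned(self, table):
        assert set(table.class_map) == CANONICAL_RESIDUES

    def test_destabilizing_and_stabilizing_sets(self, table):
        assert table.destabilizing_set() == DESTABILIZING
        assert table.stabilizing_set() == STABILIZING
        assert len(DESTABILIZING) == 13 and len(STABILIZING) == 7

    @pytest.mark.parametrize(
        "residues, expected",
        [
            ("RKH", ResidueClass.PRIMARY_TYPE1),
            ("FWYLI", ResidueClass.PRIMARY_TYPE2),
            ("DE", ResidueClass.SECONDARY),
            ("NQC", ResidueClass.TERTIARY),
            ("AGMPSTV", ResidueClass.STABILIZING),
            ("BJOUXZ", ResidueClass.UNKNOWN),
        ],
    )
    def test_class_assignment(self, table, residues, expected):
        for r in residues:
            result = classify_residue(r, table)
            assert result.residue_class is expected
            assert result.destabilizing == expected.destabilizing

    @pytest.mark.parametrize(
        "residues, site",
        [
            ("RKHDENQC", RecogninSite.TYPE1_SITE),
            ("FWYLI", RecogninSite.TYPE2_SITE),
            ("AGMPSTVX", RecogninSite.NONE),
        ],
    )
    def test_recognin_site(self, table, residues, site):
        for r in residues:
            assert classify_residue(r, table).recognin_site is site


class TestClassify:
    def test_asparagine_is_tertiary_with_deamidation_cascade(self, table):
        res = classify_residue("N", table)
        assert res.residue_class is ResidueClass.TERTIARY
        assert res.destabilizing
        assert [str(s) for s in res.cascade] == ["NTAN1:N>D", "ATE1:D>R"]
        assert res.recognin_site is RecogninSite.TYPE1_SITE

    def test_valine_is_stabilizing_control(self, table):
        res = classify_residue("V", table)
        assert res.residue_class is ResidueClass.STABILIZING
        assert not res.destabilizing
        assert res.cascade == ()

    def test_isoleucine_is_primary_type2(self, table):
        res = classify_residue("I", table)
        assert res.residue_class is ResidueClass.PRIMARY_TYPE2
        assert res.destabilizing

    def test_ambiguity_code_unknown_not_destabilizing(self, table):
        res = classify_residue("X", table)
        assert res.residue_class is ResidueClass.UNKNOWN
        assert not res.destabilizing

    @pytest.mark.parametrize("bad", ["", "NN", "N "])
    def test_non_single_character_rejected(self, table, bad):
        with pytest.raises(ValueError):
            classify_residue(bad, table)

    def test_acetylated_override_forces_unknown(self, table):
        res = classify_residue("R", table, acetylated=True)
        assert res.residue_class is ResidueClass.UNKNOWN
        assert not res.destabilizing

    def test_pure_function(self, table):
        assert classify_residue("Q", table) == classify_residue("Q", table)


class TestCascades:
    @pytest.mark.parametrize(
        "residue, expected",
        [
            ("N", ["NTAN1:N>D", "ATE1:D>R"]),
            ("Q", ["NTAQ1:Q>E", "ATE1:E>R"]),
            ("C", [f"CYS_OXIDATION:C>{OXIDIZED_CYS}", f"ATE1:{OXIDIZED_CYS}>R"]),
            ("D", ["ATE1:D>R"]),
            ("E", ["ATE1:E>R"]),
            ("R", []),
            ("V", []),
            ("F", []),
        ],
    )
    def test_cascade_paths(self, table, residue, expected):
        assert [str(s) for s in cascade_path(residue, table)] == expected

    def test_cascades_nonempty_exactly_for_secondary_tertiary(self, table):
        with_cascade = {r for r in CANONICAL_RESIDUES if cascade_path(r, table)}
        assert with_cascade == set("DENQC")

    def test_closure_terminates_at_arginine_within_two_steps(self, table):
        for residue in "DENQC":
            steps = cascade_path(residue, table)
            assert 1 <= len(steps) <= 2
            final = steps[-1].output_residue
            assert classify_residue(final, table).residue_class is \
                ResidueClass.PRIMARY_TYPE1

    def test_unknown_residue_query_error(self, table):
        with pytest.raises(KeyError):
            cascade_path("X", table)


class TestMetExcision:
    @pytest.mark.parametrize(
        "seq, mature, excised",
        [
            ("MASK", "A", True),
            ("MKLE", "M", False),
            ("ACDE", "A", False),
            ("MV", "V", True),
            ("MM", "M", False),
        ],
    )
    def test_small_side_chain_rule(self, table, seq, mature, excised):
        res = apply_met_excision(seq, table)
        assert (res.mature_first_residue, res.excised) == (mature, excised)

    def test_too_short_rejected(self, table):
        with pytest.raises(ValueError):
            apply_met_excision("M", table)

    def test_specificity_set_is_configurable(self, table):
        custom = RuleTable(table.class_map, table.cascades, table.recognin_site,
                           met_excision_set=frozenset("K"))
        assert apply_met_excision("MKLE", custom).excised
        assert not apply_met_excision("MASK", custom).excised


class TestRuleTableConfig:
    def test_yaml_roundtrip_equivalent(self, table, tmp_path):
        doc = {
            "classes": {
                cls.value: sorted(
                    r for r, c in table.class_map.items() if c is cls
                )
                for cls in ResidueClass
                if cls is not ResidueClass.UNKNOWN
            },
            "cascades": {
                r: [{"enzyme": s.enzyme, "to": s.output_residue} for s in steps]
                for r, steps in table.cascades.items()
            },
            "recognin": {
                site.value: sorted(
                    r for r, s in table.recognin_site.items() if s is site
                )
                for site in (RecogninSite.TYPE1_SITE, RecogninSite.TYPE2_SITE)
            },
        }
        path = tmp_path / "rules.yaml"
        path.write_text(yaml.safe_dump(doc))
        loaded = RuleTable.from_yaml(path)
        assert loaded.class_map == table.class_map
        assert loaded.cascades == table.cascades
        assert loaded.recognin_site == table.recognin_site

    def test_incomplete_partition_rejected(self):
        with pytest.raises(RuleTableError):
            RuleTable({"A": ResidueClass.STABILIZING}, {}, {})

    def test_cascade_must_terminate_at_primary_type1(self, table):
        bad = dict(table.cascades)
        bad["D"] = (EnzymaticStep("ATE1", "D", "G"),)
        with pytest.raises(RuleTableError):
            RuleTable(table.class_map, bad, table.recognin_site)

    def test_missing_cascade_for_secondary_rejected(self, table):
        bad = {r: s for r, s in table.cascades.items() if r != "E"}
        with pytest.raises(RuleTableError):
            RuleTable(table.class_map, bad, table.recognin_site)

    def test_step_must_change_residue(self):
        with pytest.raises(ValueError):
            EnzymaticStep("ATE1", "D", "D")
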