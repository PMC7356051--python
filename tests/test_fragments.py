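"""Cleavage plumbing: fragments, octamers, context windows, annotation."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ndegron.fragments import (
    AnnotationSummary,
    CleavageSite,
    SiteError,
    SubstrateRecord,
    annotate,
    cleave,
    extract_octamer,
    extract_window,
)
from ndegron.simulate import SubstrateGenConfig, gen_substrates

SEQ = "ACDEFGHIKL"

protein = st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=2, max_size=120)


class TestCleave:
    @pytest.mark.parametrize(
        "p1, expected",
        [(4, ("ACDE", "FGHIKL")), (1, ("A", "CDEFGHIKL")), (9, ("ACDEFGHIK", "L"))],
    )
    def test_examples(self, p1, expected):
        assert cleave(SEQ, p1) == expected

    def test_minimal_two_residue_case(self):
        assert cleave("AR", 1) == ("A", "R")

    @pytest.mark.parametrize("p1", [0, 10, 11])
    def test_no_c_terminal_fragment_is_site_error(self, p1):
        with pytest.raises(SiteError):
            cleave(SEQ, p1)

    @given(protein, st.integers(1, 200))
    @settings(max_examples=150, derandomize=True)
    def test_reconstruction(self, seq, p1):
        if not 1 <= p1 < len(seq):
            return
        n_frag, c_frag = cleave(seq, p1)
        assert n_frag + c_frag == seq
        assert len(n_frag) == p1


class TestOctamer:
    @pytest.mark.parametrize(
        "p1, expected",
        [(4, "ACDEFGHI"), (2, "--ACDEFG"), (9, "GHIKL---"), (1, "---ACDEF")],
    )
    def test_examples_with_terminal_padding(self, p1, expected):
        assert extract_octamer(SEQ, p1) == expected

    @given(protein, st.integers(1, 200))
    @settings(max_examples=150, derandomize=True)
    def test_p1prime_sits_at_fifth_position(self, seq, p1):
        if not 1 <= p1 < len(seq):
            return
        octamer = extract_octamer(seq, p1)
        assert len(octamer) == 8
        assert octamer[4] == seq[p1]  # 0-based index p1 == 1-based P1'


class TestWindow:
    def test_interior_site_gives_60_residue_window(self):
        seq = "".join("ACDEFGHIKLMNPQRSTVWY"[i % 20] for i in range(200))
        window, offset, truncated = extract_window(seq, 100, flank=26)
        assert len(window) == 60
        assert offset == 31
        assert not truncated
        assert window == seq[70:130]

    def test_n_terminal_truncation_offset(self):
        # independent index walk: window covers residues 1..p1+4+flank,
        # so P1' (residue 11) sits at offset 11
        seq = "ACDEFGHIKLMNPQRSTVWY" * 5
        window, offset, truncated = extract_window(seq, 10, flank=26)
        assert truncated
        assert window == seq[: 10 + 4 + 26]
        assert offset == 10 - max(1, 10 - 3 - 26) + 2 == 11
        assert window[offset - 1] == seq[10]

    def test_flank_zero_equals_unpadded_octamer_span(self):
        window, offset, truncated = extract_window(SEQ, 2, flank=0)
        assert window == "ACDEFG"
        assert window == extract_octamer(SEQ, 2).strip("-")
        assert window[offset - 1] == SEQ[2]

    def test_invalid_site_and_flank(self):
        with pytest.raises(SiteError):
            extract_window(SEQ, 10)
        with pytest.raises(ValueError):
            extract_window(SEQ, 4, flank=-1)

    @given(protein, st.integers(1, 200), st.integers(0, 40))
    @settings(max_examples=200, derandomize=True)
    def test_window_containment(self, seq, p1, flank):
        if not 1 <= p1 < len(seq):
            return
        window, offset, truncated = extract_window(seq, p1, flank)
        assert window in seq
        assert window[offset - 1] == seq[p1]
        assert len(window) <= 8 + 2 * flank
        assert truncated == (len(window) < 8 + 2 * flank)


class TestAnnotate:
    def test_panel_screen_counts(self, panel_bundle, table):
        substrates, sites, _ = panel_bundle
        annotations, summary, errors = annotate(substrates, sites, table)
        assert not errors
        assert summary.n_sites == 15
        assert summary.n_fragments == 14
        assert summary.n_fragments_destabilizing == 14
        assert summary.fraction_destabilizing == 1.0
        assert summary.class_counts.get("UNKNOWN", 0) == 0

    def test_caspase1_subset_yields_nine_fragments(self, panel_bundle, table):
        substrates, sites, _ = panel_bundle
        subset = [s for s in sites if s.protease == "caspase-1"]
        _, summary, _ = annotate(substrates, subset, table)
        assert summary.n_fragments == 9
        assert summary.n_fragments_destabilizing == 9

    def test_panel_p1prime_residues_as_reported(self, panel_bundle, table):
        substrates, sites, _ = panel_bundle
        annotations, _, _ = annotate(substrates, sites, table)
        assert sorted(a.p1prime_residue for a in annotations) == sorted(
            "N Q Q C Y Y E L C L I I I E Y".split()
        )
        assert [a.p1prime_residue for a in annotations].count("I") == 3

    def test_synthetic_classes_equal_generator_truth(self, table):
        subs, sites, truth = gen_substrates(
            SubstrateGenConfig(seed=7, n_substrates=40, p_destab=0.5)
        )
        annotations, _, errors = annotate(subs, sites, table)
        assert not errors
        truth_by_key = {(t.substrate_id, t.p1_position): t for t in truth.sites}
        assert len(annotations) == len(truth.sites)
        for a in annotations:
            t = truth_by_key[(a.site.substrate_id, a.site.p1_position)]
            assert a.p1prime_residue == t.p1prime_residue
            assert a.classification.residue_class.value == t.residue_class
            assert a.classification.destabilizing == t.destabilizing

    def test_empty_site_list(self, table):
        annotations, summary, errors = annotate([], [], table)
        assert annotations == [] and errors == []
        assert summary.n_sites == 0 and summary.fraction_destabilizing == 0.0

    def test_bad_sites_become_error_records_and_run_continues(self, table):
        subs = [SubstrateRecord("P1", "ACDEFGHIKL")]
        sites = [
            CleavageSite("P1", "caspase-1", 4),
            CleavageSite("MISSING", "caspase-1", 2),
            CleavageSite("P1", "caspase-1", 10),  # no C-terminal fragment
        ]
        annotations, summary, errors = annotate(subs, sites, table)
        assert len(annotations) == 1 and len(errors) == 2
        assert summary.n_errors == 2
        assert any("unknown substrate_id" in e.reason for e in errors)
        assert any("C-terminal" in e.reason for e in errors)

    def test_fraction_invariant_under_input_order(self, table):
        subs, sites, _ = gen_substrates(
            SubstrateGenConfig(seed=11, n_substrates=25, p_destab=0.3)
        )
        _, fwd, _ = annotate(subs, sites, table)
        _, rev, _ = annotate(subs, list(reversed(sites)), table)
        assert fwd == rev

    def test_acetylated_site_reported_unknown_and_excluded(self, table):
        subs = [SubstrateRecord("P1", "ACDEFRHIKL")]
        sites = [CleavageSite("P1", "caspase-1", 4, acetylated=True),
                 CleavageSite("P1", "caspase-1", 5)]
        annotations, summary, _ = annotate(subs, sites, table)
        assert summary.n_sites == 2
        assert summary.n_classified == 1
        assert summary.fraction_destabilizing == 1.0  # the lone classified R

    def test_class_counts_sum_to_n_sites(self, table):
        subs, sites, _ = gen_substrates(
            SubstrateGenConfig(seed=3, n_substrates=30, p_destab=0.4)
        )
        _, summary, _ = annotate(subs, sites, table)
        assert sum(summary.class_counts.values()) == summary.n_sites
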