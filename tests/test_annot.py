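"""Structural character systems: landmarks, B-C loop codes, intron phases,
WPD calls, YxN motifs, and full planted-truth recovery."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rptp.annot import (BCLOOP_COLORS, anchor_landmarks, bcloop_code,
                        call_wpd, character_table, fn3_intron_code,
                        fn3_scaffold, intron_phases, ptp_scaffold, scan_yxn)
from rptp.records import DomainAnnotation, GeneModel, ProteinRecord
from rptp.simulate import default_config, simulate_family


class TestAnchorLandmarks:
    def test_self_alignment_maps_landmarks_exactly(self):
        sc = fn3_scaffold()
        assert anchor_landmarks(sc.sequence, sc) == sc.landmarks

    def test_insertion_shifts_downstream_landmarks(self):
        sc = fn3_scaffold()
        mod = sc.sequence[:5] + "QQ" + sc.sequence[5:]
        lm = anchor_landmarks(mod, sc)
        assert lm == {k: v + 2 for k, v in sc.landmarks.items()}

    def test_mutated_landmark_is_absent(self):
        sc = fn3_scaffold()
        w = sc.landmarks["W"]
        mut = sc.sequence[:w] + "L" + sc.sequence[w + 1:]
        lm = anchor_landmarks(mut, sc)
        assert lm["W"] is None and lm["Y"] == sc.landmarks["Y"]


def _loop_domain(n: int, m: int, filler: str = "A") -> str:
    """Scaffold variant whose loop has n residues W..G and m residues G..Y."""
    sc = fn3_scaffold()
    w, y = sc.landmarks["W"], sc.landmarks["Y"]
    return (sc.sequence[:w] + "W" + filler * n + "G" + filler * m + "Y"
            + sc.sequence[y + 1:])


class TestBCLoopCode:
    @pytest.mark.parametrize("code,color", sorted(BCLOOP_COLORS.items()))
    def test_color_table(self, code, color):
        import re
        n, m = map(int, re.fullmatch(r"W(\d+)G(\d+)Y", code).groups())
        bc = bcloop_code(_loop_domain(n, m))
        assert bc.code == code and bc.color == color

    def test_w4g4y_spans_nine_residues(self):
        bc = bcloop_code(_loop_domain(4, 4))
        assert bc.y_pos - bc.w_pos - 1 == 9

    def test_w7g4y_spans_twelve_residues(self):
        bc = bcloop_code(_loop_domain(7, 4))
        assert bc.y_pos - bc.w_pos - 1 == 12

    def test_residue_accounting_identity(self):
        # n + m + 1 == loop length (the G accounts for one residue)
        for n, m in [(4, 4), (7, 4), (9, 2), (5, 4), (2, 11)]:
            bc = bcloop_code(_loop_domain(n, m))
            assert bc.g_pos - bc.w_pos - 1 == n
            assert bc.y_pos - bc.g_pos - 1 == m
            assert n + m + 1 == bc.y_pos - bc.w_pos - 1

    def test_no_glycine_codes_white_with_span(self):
        bc = bcloop_code(_loop_domain(9, 0)[:0] + _loop_domain(4, 4).replace(
            "WAAAAGAAAAY", "WAAAAAAAAAY"))
        assert bc.code == "W9Y" and bc.color == "white"

    def test_scaffold_column_selects_among_two_glycines(self):
        """Two loop glycines: the one in the scaffold's G column wins."""
        sc = fn3_scaffold()
        w, g, y = sc.landmarks["W"], sc.landmarks["G"], sc.landmarks["Y"]
        seq = list(sc.sequence)
        seq[w + 3] = "G"  # extra G left of the scaffold G column
        bc = bcloop_code("".join(seq), sc)
        assert bc.g_pos == g
        assert bc.code == "W4G4Y"

    def test_missing_anchor_codes_white_with_reason(self):
        sc = fn3_scaffold()
        w = sc.landmarks["W"]
        mut = sc.sequence[:w] + "L" + sc.sequence[w + 1:]
        bc = bcloop_code(mut, sc)
        assert bc.color == "white" and "W" in bc.reason

    def test_overlong_loop_rejected_as_misanchor(self):
        bc = bcloop_code(_loop_domain(20, 15))
        assert bc.color == "white" and "exceeds" in bc.reason


class TestIntronPhases:
    @pytest.mark.parametrize("lengths,expected", [
        ([99, 201], [(33, 0)]),
        ([100, 200], [(33, 1)]),
        ([101, 199], [(33, 2)]),
    ])
    def test_phase_arithmetic(self, lengths, expected):
        exons, pos = [], 0
        for L in lengths:
            exons.append((pos, pos + L))
            pos += L + 50
        gm = GeneModel("g", exons, "+", list(lengths))
        assert intron_phases(gm) == expected

    @given(st.lists(st.integers(1, 500), min_size=1, max_size=8))
    @settings(max_examples=60, derandomize=True)
    def test_intron_count_and_frame(self, lengths):
        total = sum(lengths)
        pad = (3 - total % 3) % 3
        lengths = list(lengths[:-1]) + [lengths[-1] + pad]
        exons, pos = [], 0
        for L in lengths:
            exons.append((pos, pos + L))
            pos += L + 10
        gm = GeneModel("g", exons, "+", lengths)
        phases = intron_phases(gm)
        assert len(phases) == len(lengths) - 1
        assert all(ph in (0, 1, 2) for _, ph in phases)
        assert sum(gm.cds_lengths) % 3 == 0


class TestFn3IntronCode:
    DOM = DomainAnnotation("p", "FN3", 100, 190, ordinal=2)

    def test_flanked_by_phase1_is_yellow(self):
        c = fn3_intron_code(self.DOM, [(100, 1), (190, 1)])
        assert c.code == "1:1" and c.color == "yellow"

    def test_internal_phase0_is_orange(self):
        c = fn3_intron_code(self.DOM, [(100, 1), (145, 0), (190, 1)])
        assert c.code == "1:0:1" and c.color == "orange"

    def test_internal_phase1_blue_phase2_black(self):
        assert fn3_intron_code(self.DOM, [(100, 1), (145, 1), (190, 1)]).color == "blue"
        assert fn3_intron_code(self.DOM, [(100, 1), (145, 2), (190, 1)]).color == "black"

    def test_juxtamembrane_multi_intron_is_grey(self):
        jm = DomainAnnotation("p", "FN3", 100, 260, ordinal=1)
        c = fn3_intron_code(jm, [(100, 1), (150, 1), (200, 2), (260, 1)],
                            juxtamembrane=True)
        assert c.code == "1:1:2:1" and c.color == "grey"

    def test_absent_upstream_is_open_sided_not_phase0(self):
        c = fn3_intron_code(self.DOM, [(145, 0), (190, 1)])
        assert c.open_upstream and c.upstream_phase is None
        assert c.code == "0:1"
        assert c.color == "white"

    def test_boundary_introns_count_as_flanking(self):
        c = fn3_intron_code(self.DOM, [(100, 2), (190, 0)])
        assert c.internal == [] and (c.upstream_phase, c.downstream_phase) == (2, 0)

    def test_translation_invariance(self):
        shift = 57
        dom2 = DomainAnnotation("p", "FN3", 100 + shift, 190 + shift, ordinal=2)
        phases = [(100, 1), (145, 0), (190, 1)]
        shifted = [(p + shift, ph) for p, ph in phases]
        assert fn3_intron_code(self.DOM, phases).code == \
            fn3_intron_code(dom2, shifted).code

    def test_flank_search_respects_neighbor_boundaries(self):
        # an intron belonging to the previous domain's span is not a flank
        c = fn3_intron_code(self.DOM, [(80, 1), (190, 1)], prev_boundary=90)
        assert c.open_upstream


class TestCallWPD:
    def test_scaffold_calls_itself_wpd(self):
        sc = ptp_scaffold()
        call = call_wpd(sc.sequence, sc)
        assert call.triplet == "WPD" and call.cls == "WPD"

    @pytest.mark.parametrize("triplet,cls", [
        ("WPE", "WPE"), ("WVD", "other"), ("WTD", "other"),
        ("WPQ", "other"), ("WSV", "other"), ("WPI", "other")])
    def test_variant_triplets(self, triplet, cls):
        sc = ptp_scaffold()
        off = sc.landmarks["WPD"]
        seq = sc.sequence[:off] + triplet + sc.sequence[off + 3:]
        call = call_wpd(seq, sc)
        assert (call.triplet, call.cls) == (triplet, cls)

    def test_unrelated_sequence_yields_unanchored_other(self):
        call = call_wpd("QQ" * 80, ptp_scaffold())
        assert call.triplet == "???" and call.cls == "other"
        assert "identity" in call.warning


class TestScanYxn:
    def test_canonical_motif(self):
        rep = scan_yxn(ProteinRecord("x", "MMMMAAYANA"), 4)
        assert rep.motifs == [(6, "YxN")] and rep.pattern == "YxN"

    def test_non_canonical_tyrosine(self):
        rep = scan_yxn(ProteinRecord("x", "MMMMAAYAQ"), 4)
        assert rep.motifs == [(6, "otherY")] and rep.pattern == "otherY"

    def test_tail_without_tyrosine(self):
        rep = scan_yxn(ProteinRecord("x", "MYMMAAAQA"), 4)
        assert rep.motifs == [] and rep.pattern == "none"

    def test_terminal_tyrosine_cannot_be_yxn(self):
        rep = scan_yxn(ProteinRecord("x", "MMMMAY"), 4)
        assert rep.motifs == [(5, "otherY")]


class TestPlantedRecovery:
    def test_all_planted_characters_recovered(self):
        """Across four independently simulated families (>= 200 FN3
        domains), every planted character is recovered exactly."""
        n_domains = 0
        cols = ["wpd_triplet", "wpd_class", "yxn_pattern",
                "bcloop_1", "bcloop_2", "bcloop_3",
                "introns_1", "introns_2", "introns_3"]
        for seed in (0, 1, 2, 3):
            fam = simulate_family(default_config(seed=seed))
            table = character_table(fam.proteins, fam.domains,
                                    fam.gene_models)
            for pid in fam.truth.index:
                for col in cols:
                    assert str(table.loc[pid, col]) == \
                        str(fam.truth.loc[pid, col]), (seed, pid, col)
            n_domains += sum(1 for d in fam.domains if d.kind == "FN3")
        assert n_domains >= 200

    def test_missing_gene_models_degrade_to_question_marks(self, family):
        table = character_table(family.proteins, family.domains, None)
        assert (table[["introns_1", "introns_2", "introns_3"]] == "?").all().all()
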