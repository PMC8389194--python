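"""Coordinate arithmetic: model construction, HGVS rendering, round trips,
reading-frame checks."""

import pytest
from hypothesis import given, settings, strategies as st

from splicecat import (HgvsPosition, ModelError, CoordinateError,
                       OutsideTranscriptError, build_model, read_model_tsv,
                       read_model_gtf, write_model_tsv)
from splicecat.simulate import make_toy_model


class TestBuildModel:
    def test_cdna_spans_follow_contiguity(self):
        m = build_model("G", "T.1", "c", "+",
                        [(101, 200), (301, 350), (401, 480)],
                        cds_start=11, cds_end=220)
        assert m.cds_start == 11
        assert m.exon(2).cdna_start == 101 and m.exon(2).cdna_end == 150
        assert m.tx_length == 230

    def test_minus_strand_reverses_exon_order(self):
        m = build_model("G", "T.1", "c", "-",
                        [(101, 200), (301, 350), (401, 480)],
                        cds_start=11, cds_end=220)
        assert m.exon(1).genomic_start == 401  # genomically last span is exon 1
        assert m.tx_length == 230

    @pytest.mark.parametrize("exons,err", [
        ([(1, 100)], "at least 2"),
        ([(1, 100), (50, 150)], "overlap"),
        ([(1, 100), (200, 150)], "reversed"),
    ])
    def test_invalid_exon_layouts_rejected(self, exons, err):
        with pytest.raises(ModelError, match=err):
            build_model("G", "T.1", "c", "+", exons, cds_start=1, cds_end=10)

    def test_cds_outside_exons_rejected(self):
        with pytest.raises(ModelError):
            build_model("G", "T.1", "c", "+", [(1, 100), (201, 300)],
                        cds_start=1, cds_end=500)
        with pytest.raises(ModelError):
            build_model("G", "T.1", "c", "+", [(1, 100), (201, 300)],
                        cds_genomic=(50, 150))


class TestHgvsPosition:
    @given(anchor=st.integers(-500, 500).filter(lambda a: a != 0),
           utr3=st.booleans(),
           offset=st.integers(-300, 300))
    @settings(max_examples=200, deadline=None)
    def test_format_parse_identity(self, anchor, utr3, offset):
        if utr3 and anchor < 0:
            anchor = -anchor
        pos = HgvsPosition(anchor=anchor, utr3=utr3, intron_offset=offset)
        assert HgvsPosition.parse(str(pos)) == pos

    @pytest.mark.parametrize("text,anchor,utr3,offset", [
        ("290+2456", 290, False, 2456),
        ("172-479", 172, False, -479),
        ("*16", 16, True, 0),
        ("-30", -30, False, 0),
        ("r.1109", 1109, False, 0),
    ])
    def test_parse_examples(self, text, anchor, utr3, offset):
        pos = HgvsPosition.parse(text)
        assert (pos.anchor, pos.utr3, pos.intron_offset) == (anchor, utr3, offset)

    def test_position_zero_rejected(self):
        with pytest.raises(CoordinateError):
            HgvsPosition(anchor=0)


class TestCoordinateConversion:
    def test_utr_anchor_rendering(self, toy4):
        # 5 nt 5'UTR: first transcript base renders as -5
        first_g = toy4.transcript_to_genomic(1)
        assert str(toy4.genomic_to_hgvs(first_g)) == "-5"
        last_g = toy4.transcript_to_genomic(toy4.tx_length)
        assert str(toy4.genomic_to_hgvs(last_g)) == "*5"

    def test_intronic_offsets_split_at_midpoint(self, toy4):
        # intron length 30: positions 1..15 render +k, 16..30 render -k
        donor = str(toy4.hgvs_anchor(toy4.donor_t(1)))
        acceptor = str(toy4.hgvs_anchor(toy4.acceptor_t(1)))
        assert str(toy4.intron_pos_hgvs(1, 15)) == f"{donor}+15"
        assert str(toy4.intron_pos_hgvs(1, 16)) == f"{acceptor}-15"

    def test_odd_intron_midpoint_goes_to_donor_side(self):
        m = make_toy_model(2, 20, 31, utr5_len=0, utr3_len=0)
        assert str(m.intron_pos_hgvs(1, 16)).endswith("+16")
        assert str(m.intron_pos_hgvs(1, 17)).endswith("-15")

    def test_round_trip_every_base(self, toy4):
        lo, hi = toy4.genomic_span
        for g in range(lo, hi + 1):
            assert toy4.hgvs_to_genomic(toy4.genomic_to_hgvs(g)) == g

    def test_round_trip_every_base_minus_strand(self, toy4_minus):
        lo, hi = toy4_minus.genomic_span
        for g in range(lo, hi + 1):
            pos = toy4_minus.genomic_to_hgvs(g)
            assert toy4_minus.hgvs_to_genomic(pos) == g

    def test_strand_symmetry(self, toy4, toy4_minus):
        lo, hi = toy4.genomic_span
        plus = sorted(str(toy4.genomic_to_hgvs(g)) for g in range(lo, hi + 1))
        lo, hi = toy4_minus.genomic_span
        minus = sorted(str(toy4_minus.genomic_to_hgvs(g)) for g in range(lo, hi + 1))
        assert plus == minus

    def test_outside_transcript_signalled(self, toy4):
        lo, hi = toy4.genomic_span
        with pytest.raises(OutsideTranscriptError):
            toy4.genomic_to_hgvs(lo - 1)
        with pytest.raises(OutsideTranscriptError):
            toy4.genomic_to_hgvs(hi + 1)

    def test_offset_exceeding_intron_rejected(self, toy4):
        donor = toy4.hgvs_anchor(toy4.donor_t(1))
        from dataclasses import replace
        with pytest.raises(CoordinateError):
            toy4.hgvs_to_genomic(replace(donor, intron_offset=31))

    def test_utr3_beyond_transcript_rejected(self, toy4):
        with pytest.raises(CoordinateError):
            toy4.hgvs_to_genomic(HgvsPosition(anchor=999, utr3=True))

    def test_offset_must_hang_from_boundary(self, toy4):
        with pytest.raises(CoordinateError):
            # interior exonic base cannot carry an intronic offset
            toy4.hgvs_to_genomic(HgvsPosition(anchor=3, intron_offset=5))


class TestStk11Fixture:
    def test_exon1_donor_is_r290(self, stk11_model):
        g = stk11_model.transcript_to_genomic(stk11_model.donor_t(1))
        assert str(stk11_model.genomic_to_hgvs(g)) == "290"

    def test_intron1_base_2456_renders_plus_offset(self, stk11_model):
        g = stk11_model.intron_pos_to_genomic(1, 2456)
        assert str(stk11_model.genomic_to_hgvs(g)) == "290+2456"

    def test_first_intronic_base_after_exon1(self, stk11_model):
        g = stk11_model.hgvs_to_genomic("290+1")
        kind, intron, p = stk11_model.locate_genomic(g)
        assert (kind, intron, p) == ("intron", 1, 1)

    def test_nine_canonical_introns(self, stk11_model):
        assert stk11_model.n_introns == 9

    def test_nbn_acceptor_offset_on_minus_strand(self, nbn_model):
        # 172-479: 479 bases upstream (transcript orientation) of the exon-3
        # acceptor; on the minus strand that is genomically downstream
        g = nbn_model.hgvs_to_genomic("172-479")
        acceptor_g = nbn_model.transcript_to_genomic(nbn_model.acceptor_t(2))
        assert str(nbn_model.genomic_to_hgvs(g)) == "172-479"
        assert abs(g - acceptor_g) == 479


class TestDeletionFrame:
    def test_nbn_exon12_deletion_in_frame(self, nbn_model):
        res = nbn_model.deletion_frame("1846", "1914")
        assert res == {"in_frame": True, "deleted_length": 69}

    def test_nbn_exon9_deletion_frameshift(self, nbn_model):
        res = nbn_model.deletion_frame("995", "1124")
        assert res == {"in_frame": False, "deleted_length": 130}

    def test_single_base_deletion(self, nbn_model):
        res = nbn_model.deletion_frame("481", "481")
        assert res == {"in_frame": False, "deleted_length": 1}

    def test_utr_touching_deletion_never_in_frame(self, stk11_model):
        res = stk11_model.deletion_frame("1109", "*16")
        assert res["deleted_length"] == 210
        assert res["in_frame"] is False

    def test_intronic_positions_rejected(self, stk11_model):
        with pytest.raises(CoordinateError):
            stk11_model.deletion_frame("290+1", "291")

    def test_frame_matches_mod3_for_coding_spans(self, toy4):
        cds_anchor = lambda t: toy4.hgvs_anchor(t)
        for t1 in range(toy4.cds_start, toy4.cds_end + 1):
            for t2 in range(t1, toy4.cds_end + 1):
                res = toy4.deletion_frame(cds_anchor(t1), cds_anchor(t2))
                assert res["in_frame"] == ((t2 - t1 + 1) % 3 == 0)


class TestModelIO:
    def test_tsv_round_trip(self, tmp_path, stk11_model):
        p = tmp_path / "m.tsv"
        write_model_tsv(stk11_model, p)
        again = read_model_tsv(p)
        assert again == stk11_model

    def test_gtf_reader(self, tmp_path, toy4):
        lines = []
        for e in toy4.exons:
            lines.append(f"chrT\tx\texon\t{e.genomic_start}\t{e.genomic_end}\t.\t+\t.\t"
                         f'gene_name "TOY"; transcript_id "TOY.1";')
        cds_g1 = toy4.transcript_to_genomic(toy4.cds_start)
        cds_g2 = toy4.transcript_to_genomic(toy4.cds_end)
        lines.append(f"chrT\tx\tCDS\t{cds_g1}\t{cds_g2}\t.\t+\t.\t"
                     f'gene_name "TOY"; transcript_id "TOY.1";')
        p = tmp_path / "m.gtf"
        p.write_text("\n".join(lines) + "\n")
        m = read_model_gtf(p)
        assert m.cds_start == toy4.cds_start
        assert m.cds_end == toy4.cds_end
        assert [e.genomic_start for e in m.exons] == [e.genomic_start for e in toy4.exons]
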