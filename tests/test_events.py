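"""Classification, pairing, naming, consequence and quantification logic.

The centrepiece is an exhaustive donor/acceptor grid over a toy model,
checked against an independently written truth table.
"""

import pytest
from hypothesis import given, settings, strategies as st

from splicecat import (JunctionRecord, ThresholdPolicy, build_catalog,
                       classify_junction, consequence_to_junctions,
                       event_from_consequence, junction_percentage,
                       merge_samples, name_event, pair_cryptic_junctions,
                       rna_consequence, apply_threshold)
from splicecat.events import assign_letters, SpliceEvent
from splicecat.simulate import make_toy_model
from splicecat.transcript import CoordinateError


# --------------------------------------------------------------------------
# Brute-force oracle: a second, independent implementation of the
# classification rules, written directly from the rule statement over
# literal genomic coordinates.
# --------------------------------------------------------------------------

def oracle_kind(model, g_donor, g_acceptor):
    """Expected event class for a junction whose last retained bases are
    g_donor (5') and g_acceptor (3').  Returns None for uninterpretable
    combinations (acceptor not after donor)."""
    exon_spans = [(e.genomic_start, e.genomic_end) for e in model.exons]
    n = len(exon_spans)

    def locate(g):
        for i, (s, e) in enumerate(exon_spans):
            if s <= g <= e:
                return ("exon", i)
        for i in range(n - 1):
            if exon_spans[i][1] < g < exon_spans[i + 1][0]:
                return ("intron", i)
        return None

    ld, la = locate(g_donor), locate(g_acceptor)
    if ld is None or la is None or g_acceptor <= g_donor + 1:
        return None

    def is_utr(g):  # exonic base in UTR?
        t = model.locate_genomic(g)[2]
        return t < model.cds_start or t > model.cds_end

    # deletion entirely inside UTR (no retained intron sequence) -> terminal
    deleted_exonic = [g for g in range(g_donor + 1, g_acceptor)
                      if locate(g) and locate(g)[0] == "exon"]
    retains_intron = (ld[0] == "intron" or la[0] == "intron")

    if ld[0] == "exon" and la[0] == "exon":
        ed, ea = ld[1], la[1]
        d_canon = ed < n - 1 and g_donor == exon_spans[ed][1]
        a_canon = ea > 0 and g_acceptor == exon_spans[ea][0]
        if d_canon and a_canon:
            if ea == ed + 1:
                return "canonical"
            skipped = ea - ed - 1
            return "exon_skip" if skipped == 1 else "multi_exon_skip"
        if deleted_exonic and all(is_utr(g) for g in deleted_exonic):
            return "terminal_modification"
        if d_canon:
            return "exonic_acceptor_shift" if ea == ed + 1 else "mixed"
        if a_canon:
            return "exonic_donor_shift" if ea == ed + 1 else "mixed"
        return "mixed"

    if deleted_exonic and not retains_intron and \
            all(is_utr(g) for g in deleted_exonic):
        return "terminal_modification"

    if ld[0] == "exon" and la[0] == "intron":
        ed, ia = ld[1], la[1]
        d_canon = g_donor == exon_spans[ed][1]
        if d_canon and ia == ed:
            return "intronic_acceptor_shift"
        return "mixed"
    if ld[0] == "intron" and la[0] == "exon":
        idx, ea = ld[1], la[1]
        a_canon = g_acceptor == exon_spans[ea][0]
        if a_canon and ea == idx + 1:
            return "intronic_donor_shift"
        return "mixed"
    return "mixed"


class TestClassificationOracle:
    def test_exhaustive_grid_matches_brute_force(self):
        """Every (donor, acceptor) base pair over toy models with 3..5 exons
        classifies identically to the independent truth table."""
        for n_exons in (3, 4, 5):
            model = make_toy_model(n_exons, 20, 30, utr5_len=5, utr3_len=5)
            lo, hi = model.genomic_span
            checked = 0
            for gd in range(lo, hi + 1):
                for ga in range(gd + 2, hi + 1):
                    expected = oracle_kind(model, gd, ga)
                    if expected is None:
                        continue
                    rec = JunctionRecord(model.chrom, gd + 1, ga - 1, 1,
                                         unique_reads=1)
                    try:
                        got = classify_junction(model, rec).kind
                    except Exception as exc:  # full-intron retention edge
                        got = f"error:{type(exc).__name__}"
                    assert got == expected, (n_exons, gd, ga, got, expected)
                    checked += 1
            assert checked > 1000


class TestClassifyExamples:
    def test_canonical_junction(self, stk11_model):
        s, e = stk11_model.intron_genomic(3)
        ev = classify_junction(stk11_model,
                               JunctionRecord("chrS", s, e, 1, unique_reads=1))
        assert ev.kind == "canonical"
        assert ev.introns_replaced == (3,)

    def test_exon4_skip(self, stk11_model):
        (s, e), = consequence_to_junctions(stk11_model, "r.465_597del")
        ev = classify_junction(stk11_model,
                               JunctionRecord("chrS", s, e, 1, unique_reads=1))
        assert ev.kind == "exon_skip"
        assert ev.exons_involved == (4,)
        assert ev.introns_replaced == (3, 4)

    def test_outside_junction_excluded_with_note(self, stk11_model):
        rec = JunctionRecord("chrS", 5, 50, 1, unique_reads=9)
        matrix = merge_samples({"A": [rec]})
        cat = build_catalog(stk11_model, matrix)
        assert len(cat.excluded) == 1
        assert cat.excluded[0][0][:3] == ("chrS", 5, 50)


class TestCrypticPairing:
    def test_nbn_intron2_pair_yields_pseudoexon(self, nbn_model):
        ev = event_from_consequence(nbn_model, "r.171_172ins172-479_172-430")
        assert ev.kind == "cryptic_exon_inclusion"
        assert ev.cryptic_span is not None
        a, d = ev.cryptic_span
        assert (str(a), str(d)) == ("172-479", "172-430")
        # 50 nt pseudoexon
        assert ev.affected_length() == 50

    def test_unpaired_tail_retention_stays_intronic_shift(self, stk11_model):
        ev = event_from_consequence(stk11_model, "r.920_921ins921-105_921-1")
        assert ev.kind == "intronic_acceptor_shift"
        assert ev.shift_acceptor_nt == 105

    def test_pairing_via_matrix(self, toy4):
        # J1: canonical donor of intron 2 -> intronic acceptor at 10
        # J2: intronic donor at 19 -> canonical acceptor; pseudoexon 10..19
        s, e = toy4.intron_genomic(2)
        j1 = JunctionRecord(toy4.chrom, s, s + 8, 1, unique_reads=80)
        j2 = JunctionRecord(toy4.chrom, s + 19, e, 1, unique_reads=100)
        evs = [classify_junction(toy4, j) for j in (j1, j2)]
        for ev, reads in zip(evs, (80, 100)):
            ev.reads_per_sample = {"A": reads}
        cryptics, remaining = pair_cryptic_junctions(toy4, evs)
        assert len(cryptics) == 1 and not remaining
        assert cryptics[0].reads_per_sample == {"A": 80}  # min of the pair
        assert cryptics[0].cryptic == (2, 10, 19)

    def test_reversed_boundaries_stay_unpaired(self, toy4):
        s, e = toy4.intron_genomic(2)
        j1 = JunctionRecord(toy4.chrom, s, s + 18, 1, unique_reads=10)  # a=20
        j2 = JunctionRecord(toy4.chrom, s + 10, e, 1, unique_reads=10)  # d=10
        evs = [classify_junction(toy4, j) for j in (j1, j2)]
        cryptics, remaining = pair_cryptic_junctions(toy4, evs)
        assert not cryptics and len(remaining) == 2

    def test_two_pseudoexons_parsimonious(self, toy4):
        """Two non-overlapping cryptic exons in one intron give exactly two
        events under parsimonious pairing, lettered by position."""
        s, e = toy4.intron_genomic(1)
        # pseudoexon X at 5..12, Y at 20..26 (intron length 30)
        jx1 = JunctionRecord(toy4.chrom, s, s + 3, 1, unique_reads=50)
        jx2 = JunctionRecord(toy4.chrom, s + 12, e, 1, unique_reads=50)
        jy1 = JunctionRecord(toy4.chrom, s, s + 18, 1, unique_reads=200)
        jy2 = JunctionRecord(toy4.chrom, s + 26, e, 1, unique_reads=200)
        evs = [classify_junction(toy4, j) for j in (jx1, jx2, jy1, jy2)]
        for ev, reads in zip(evs, (50, 50, 200, 200)):
            ev.reads_per_sample = {"A": reads}
        cryptics, _ = pair_cryptic_junctions(toy4, evs, mode="parsimonious")
        assert sorted(c.cryptic for c in cryptics) == [(1, 5, 12), (1, 20, 26)]
        assign_letters(toy4, cryptics)
        names = sorted(name_event(toy4, c) for c in cryptics)
        assert names == ["▼1A", "▼1B"]


class TestNaming:
    @pytest.mark.parametrize("consequence,name", [
        ("r.465_597del", "Δ4"),
        ("r.291_464del", "Δ2–3"),
        ("r.1109_1113del", "Δ9q"),
        ("r.920_921ins921-105_921-1", "▼8q"),
        ("r.-272_-186del", "Δ5′UTR"),
        ("r.1109_*16del", "Δ9"),
    ])
    def test_single_event_names(self, stk11_model, consequence, name):
        ev = event_from_consequence(stk11_model, consequence)
        assert name_event(stk11_model, ev) == name

    def test_three_pseudoexons_letter_by_position(self, toy4):
        events = []
        for a, d in [(20, 25), (3, 8), (11, 15)]:
            ev = SpliceEvent(kind="cryptic_exon_inclusion", junctions=(),
                             cryptic=(3, a, d))
            from splicecat.events import _event_from_geometry
            ev = _event_from_geometry(toy4, (), (), (), cryptic=(3, a, d))
            events.append(ev)
        assign_letters(toy4, events)
        named = {ev.cryptic: name_event(toy4, ev) for ev in events}
        assert named == {(3, 3, 8): "▼3A", (3, 11, 15): "▼3B", (3, 20, 25): "▼3C"}

    def test_pq_convention_follows_tables_with_invert_switch(self, nbn_model):
        ev = event_from_consequence(nbn_model, "r.1896_1914del")  # exon 12 3' end
        assert ev.kind == "exonic_donor_shift"
        assert name_event(nbn_model, ev) == "Δ12p"
        assert name_event(nbn_model, ev, pq_invert=True) == "Δ12q"

    def test_compound_name_joins_components(self, stk11_model):
        ev = event_from_consequence(stk11_model, "r.490_653del")
        assert ev.kind == "mixed"
        assert name_event(stk11_model, ev) == "Δ4p+Δ5q"

    def test_established_names_kept_verbatim(self, stk11_model):
        ev = event_from_consequence(stk11_model, "r.290_291ins291-2149_291-2019")
        ev.established_name = "▼1C"
        assert name_event(stk11_model, ev) == "▼1C"


class TestConsequence:
    @pytest.mark.parametrize("text", [
        "r.465_597del",
        "r.290_291ins291-2149_291-2019",
        "r.1109_*16del",
        "r.-272_-186del",
        "r.920_921ins921-105_921-1",
        "r.858_862del+r.862_863ins863-125_863-103",
        "r.734del",
    ])
    def test_round_trip_from_parsed_coordinates(self, stk11_model, text):
        ev = event_from_consequence(stk11_model, text)
        assert rna_consequence(stk11_model, ev) == text

    @pytest.mark.parametrize("text", [
        "r.374delinsAC",                      # sequence-level
        "r.820_921ins921-34_921-1",           # non-adjacent anchors
        "r.1180_1181ins1108+466_1108+600",    # anchors off by an exon
        "r.2184_2185ins2185-4_2185-1ins",     # trailing garbage
    ])
    def test_malformed_descriptions_rejected(self, stk11_model, nbn_model, text):
        model = stk11_model if "1180" in text or "921" in text or "374" in text \
            else nbn_model
        with pytest.raises(CoordinateError):
            consequence_to_junctions(model, text)


class TestJunctionPercentage:
    @pytest.mark.parametrize("alt,canon,expected", [
        (10912, [293569], 3.717),
        (532, [316895, 254161], 0.186),
        (0, [293569], 0.000),
    ])
    def test_published_cells(self, alt, canon, expected):
        assert round(junction_percentage(alt, canon), 3) == expected

    def test_scale_full_expression_is_100(self):
        assert junction_percentage(500, [500]) == pytest.approx(100.0)

    def test_all_zero_canonical_flagged(self):
        with pytest.raises(ZeroDivisionError):
            junction_percentage(10, [0, 0])

    def test_per_sample_sequences_accepted(self):
        assert junction_percentage([10, 20], [[100, 100], [200, 200]]) == \
            pytest.approx(100 * 15 / 150)


class TestThreshold:
    def _event(self, counts):
        ev = SpliceEvent(kind="exon_skip",
                         junctions=(JunctionRecord("c", 10, 20, 1, unique_reads=1),))
        ev.reads_per_sample = {f"S{i}": c for i, c in enumerate(counts)}
        return ev

    def test_single_sample_failure(self):
        ev = self._event([116, 0, 0, 0, 0, 0])
        apply_threshold([ev], ThresholdPolicy())
        assert not ev.passes_threshold
        assert ev.fail_reason == "single_sample"

    def test_low_reads_failure(self):
        ev = self._event([6, 6, 6, 6, 6, 6])
        apply_threshold([ev], ThresholdPolicy())
        assert not ev.passes_threshold
        assert ev.fail_reason == "low_reads"

    def test_boundary_pass(self):
        ev = self._event([25, 25, 0, 0, 0, 0])
        apply_threshold([ev], ThresholdPolicy())
        assert ev.passes_threshold

    def test_whitelisted_junction_passes_regardless(self):
        ev = self._event([3, 0, 0, 0, 0, 0])
        apply_threshold([ev], ThresholdPolicy(whitelist=frozenset({("c", 10, 20)})))
        assert ev.passes_threshold
        assert ev.previously_published

    @given(counts=st.lists(st.integers(0, 100), min_size=1, max_size=8),
           min_reads=st.integers(1, 50), min_samples=st.integers(1, 5),
           bump_reads=st.integers(0, 20), bump_samples=st.integers(0, 3))
    @settings(max_examples=150, deadline=None)
    def test_threshold_monotonicity(self, counts, min_reads, min_samples,
                                    bump_reads, bump_samples):
        """Raising min_reads or min_samples never converts fail -> pass."""
        ev1, ev2 = self._event(counts), self._event(counts)
        apply_threshold([ev1], ThresholdPolicy(min_reads, min_samples))
        apply_threshold([ev2], ThresholdPolicy(min_reads + bump_reads,
                                               min_samples + bump_samples))
        if not ev1.passes_threshold:
            assert not ev2.passes_threshold


class TestBuildCatalog:
    def test_canonical_only_matrix(self, toy4):
        recs = []
        for i in range(1, toy4.n_introns + 1):
            s, e = toy4.intron_genomic(i)
            recs.append(JunctionRecord(toy4.chrom, s, e, 1, unique_reads=1000))
        cat = build_catalog(toy4, merge_samples({"A": recs}))
        assert all(ev.kind == "canonical" for ev in cat.events)
        assert len(cat.events) == toy4.n_introns

    def test_determinism_byte_identical(self, tmp_path, stk11_model):
        from splicecat import write_catalog_tsv
        from splicecat.fixtures import fixture_sample_records
        out = []
        for i in (1, 2):
            matrix = merge_samples(fixture_sample_records("stk11_table1"))
            cat = build_catalog(stk11_model, matrix)
            p = tmp_path / f"c{i}.tsv"
            write_catalog_tsv(cat, p)
            out.append(p.read_bytes())
        assert out[0] == out[1]

    def test_every_junction_mapped_or_excluded(self, toy4):
        s1, e1 = toy4.intron_genomic(1)
        recs = [JunctionRecord(toy4.chrom, s1, e1, 1, unique_reads=100),
                JunctionRecord(toy4.chrom, 1, 5, 1, unique_reads=3)]  # outside
        cat = build_catalog(toy4, merge_samples({"A": recs}))
        mapped = sum(len(cat.events_for_junction(k)) > 0
                     for k in [r.key for r in recs])
        assert mapped + len(cat.excluded) == len(recs)

    def test_naming_injective_for_lettered_kinds(self, stk11_catalog):
        lettered = [e for e in stk11_catalog.alternative_events()
                    if e.kind not in {"terminal_modification", "mixed"}]
        names = [e.name for e in lettered]
        assert len(names) == len(set(names))
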