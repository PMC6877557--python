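import random

import pytest
from hypothesis import given, strategies as st

from repeatspan.io_formats import PafRecord, SequenceRecord
from repeatspan.overlap_model import (BOTH, CONTAINED_1, DOVETAIL, HEAD,
                                      INTERNAL, NONE, PARTIAL, TAIL, Overlap,
                                      Params, estimate_base_accuracy,
                                      extension_score, filter_overlaps,
                                      overlap_from_paf, overlap_score)
from repeatspan.synthetic_data import naive_overlap_detect

P = Params()


def ov(**kw):
    base = dict(id1="a", id2="b", end1=TAIL, end2=HEAD, strand="+",
                ol1=5000, ol2=5000, si=0.99, len1=10000, len2=10000)
    base.update(kw)
    return Overlap(**base)


class TestScores:
    @pytest.mark.parametrize("ol1,ol2,si,expect", [
        (8000, 8000, 0.98, 7840.0),
        (7000, 7000, 1.0, 7000.0),       # perfect identity: OS = OL
        (5000, 5000, 1e-9, 5e-6),        # vanishing identity: OS -> 0
        (4000, 6000, 0.5, 2500.0),       # asymmetric aligned spans
    ])
    def test_overlap_score_values(self, ol1, ol2, si, expect):
        assert overlap_score(ov(ol1=ol1, ol2=ol2, si=si)) == pytest.approx(expect)

    @pytest.mark.parametrize("el2,oh1,oh2,expect", [
        (5000, 0, 0, 10340.0),
        (0, 0, 0, 7840.0),               # no extension: ES = OS
        (1000, 200, 100, 8190.0),
    ])
    def test_extension_score_values(self, el2, oh1, oh2, expect):
        o = ov(ol1=8000, ol2=8000, si=0.98, el2=el2, oh1=oh1, oh2=oh2)
        assert extension_score(o, "b") == pytest.approx(expect)

    def test_overlap_score_symmetric_extension_not(self):
        o = ov(el1=2000, el2=6000)
        assert overlap_score(o) == overlap_score(o)  # no side argument at all
        assert extension_score(o, "a") != extension_score(o, "b")

    @given(st.integers(1, 10 ** 5), st.integers(0, 10 ** 4),
           st.integers(0, 500), st.integers(0, 500))
    def test_extension_bounded_by_overhang_free_case(self, o_l, el, oh1, oh2):
        o = ov(ol1=o_l, ol2=o_l, el2=el, oh1=oh1, oh2=oh2)
        bound = overlap_score(o) + el / 2
        es = extension_score(o, "b")
        assert es <= bound
        assert (es == bound) == (oh1 == 0 and oh2 == 0)


class TestGeometryFromPaf:
    """Hand-drawn dovetail layouts: contig c (60 kb), read r (10 kb)."""

    SEQ_LENS = {"r": 10_000, "c": 60_000}

    def rec(self, qs, qe, ts, te, strand="+"):
        return PafRecord("r", 10_000, qs, qe, strand, "c", 60_000, ts, te,
                         qe - qs, qe - qs, 60)

    @pytest.mark.parametrize("qs,qe,ts,te,strand,er,ec,ohr,ohc,elr,elc", [
        # read head onto contig tail, forward: read extends rightwards
        (0, 5000, 55_000, 60_000, "+", HEAD, TAIL, 0, 0, 5000, 55_000),
        # read tail onto contig head, forward: read extends leftwards
        (5000, 10_000, 0, 5000, "+", TAIL, HEAD, 0, 0, 5000, 55_000),
        # reverse-strand read over the contig tail: its tail engages
        (5000, 10_000, 55_000, 60_000, "-", TAIL, TAIL, 0, 0, 5000, 55_000),
        # reverse-strand read over the contig head: its head engages
        (0, 5000, 0, 5000, "-", HEAD, HEAD, 0, 0, 5000, 55_000),
        # overhangs on both sides shrink the extensions
        (200, 5000, 55_000, 59_900, "+", HEAD, TAIL, 200, 100, 4900, 54_800),
        (5000, 9800, 100, 5000, "+", TAIL, HEAD, 200, 100, 4900, 54_800),
        # reverse-strand variants of the overhang cases
        (5000, 9800, 55_000, 59_900, "-", TAIL, TAIL, 200, 100, 4900, 54_800),
        (200, 5000, 100, 5000, "-", HEAD, HEAD, 200, 100, 4900, 54_800),
    ])
    def test_dovetail_orientations(self, qs, qe, ts, te, strand,
                                   er, ec, ohr, ohc, elr, elc):
        o = overlap_from_paf(self.rec(qs, qe, ts, te, strand), self.SEQ_LENS, P)
        assert o.kind == DOVETAIL
        assert (o.end_of("r"), o.end_of("c")) == (er, ec)
        assert (o.oh_of("r"), o.oh_of("c")) == (ohr, ohc)
        assert (o.el_of("r"), o.el_of("c")) == (elr, elc)

    def test_internal_on_both_returns_none(self):
        assert overlap_from_paf(
            self.rec(2600, 7400, 20_000, 24_800), self.SEQ_LENS, P) is None

    def test_read_contained_in_contig_interior(self):
        o = overlap_from_paf(self.rec(0, 10_000, 20_000, 30_000),
                             self.SEQ_LENS, P)
        assert o.kind == CONTAINED_1
        assert o.end_of("r") == BOTH
        assert o.end_of("c") == NONE

    def test_read_end_against_contig_interior_is_internal(self):
        o = overlap_from_paf(self.rec(0, 5000, 20_000, 25_000),
                             self.SEQ_LENS, P)
        assert o.kind == INTERNAL

    def test_same_side_pairing_is_partial(self):
        o = overlap_from_paf(self.rec(0, 5000, 0, 5000, "+"),
                             self.SEQ_LENS, P)
        assert o.kind == PARTIAL

    def test_read_read_extensions(self):
        # r1 tail over r2 head: r2 extends right by 8 kb, r1 left by 6 kb
        rec = PafRecord("r1", 10_000, 6000, 10_000, "+", "r2", 12_000,
                        0, 4000, 4000, 4000, 60)
        o = overlap_from_paf(rec, {"r1": 10_000, "r2": 12_000}, P)
        assert o.kind == DOVETAIL
        assert (o.el_of("r1"), o.el_of("r2")) == (6000, 8000)

    def test_length_disagreement_is_error(self):
        with pytest.raises(ValueError, match="disagrees"):
            overlap_from_paf(self.rec(0, 5000, 55_000, 60_000),
                             {"r": 9_000, "c": 60_000}, P)

    def test_unknown_sequence_is_error(self):
        with pytest.raises(KeyError):
            overlap_from_paf(self.rec(0, 5000, 55_000, 60_000),
                             {"r": 10_000}, P)


class TestFilters:
    def test_low_identity_overlap_dropped(self):
        keep = ov(id1="r1", id2="r2", si=0.97)
        drop = ov(id1="r1", id2="r3", si=0.965)
        kept, disc = filter_overlaps([keep, drop], {"r1", "r2", "r3"}, set(), P)
        assert kept == [keep] and not disc

    def test_interior_read_discarded_entirely(self):
        interior = Overlap(id1="r1", id2="c1", end1=BOTH, end2=NONE,
                           strand="+", ol1=9990, ol2=9990, si=0.999,
                           len1=10_000, len2=60_000, kind=CONTAINED_1)
        side = ov(id1="r1", id2="r2", si=0.99)
        kept, disc = filter_overlaps([interior, side], {"r1", "r2"}, {"c1"}, P)
        assert disc == {"r1"}
        assert kept == []  # the read's dovetail went with it

    def test_interior_read_below_identity_threshold_kept(self):
        interior = Overlap(id1="r1", id2="c1", end1=BOTH, end2=NONE,
                           strand="+", ol1=9900, ol2=9900, si=0.99,
                           len1=10_000, len2=60_000, kind=CONTAINED_1)
        side = ov(id1="r1", id2="r2", si=0.99)
        kept, disc = filter_overlaps([interior, side], {"r1", "r2"}, {"c1"}, P)
        assert disc == set() and kept == [side]

    def test_contained_reads_match_brute_force(self):
        rng = random.Random(3)
        genome = "".join(rng.choices("ACGT", k=40_000))
        ivals = [(0, 8000), (6000, 14_000), (12_000, 20_000), (18_000, 26_000),
                 (24_000, 32_000), (30_000, 38_000),
                 (7000, 12_000), (19_000, 25_000)]  # last two are contained
        reads = [SequenceRecord(f"r{s}_{e}", genome[s:e]) for s, e in ivals]
        expected = {f"r{s}_{e}" for s, e in ivals
                    if any((s2 <= s and e <= e2) and (s2, e2) != (s, e)
                           for s2, e2 in ivals)}
        paf = naive_overlap_detect(reads, min_len=500)
        lens = {r.id: r.length for r in reads}
        ovs = [o for o in (overlap_from_paf(r, lens, P) for r in paf)
               if o is not None]
        kept, disc = filter_overlaps(ovs, {r.id for r in reads}, set(), P)
        assert disc == expected

    def test_filter_is_idempotent(self):
        keep = ov(id1="r1", id2="r2", si=0.99)
        drop = ov(id1="r1", id2="r3", si=0.9)
        kept, disc = filter_overlaps([keep, drop], {"r1", "r2", "r3"}, set(), P)
        kept2, disc2 = filter_overlaps(kept, {"r1", "r2", "r3"}, set(), P)
        assert kept2 == kept and disc2 == set()


class TestBaseAccuracy:
    def test_constant_identity(self):
        ovs = [ov(id1="r1", id2="r2", si=0.99),
               ov(id1="r2", id2="r3", si=0.99)]
        alpha, eps = estimate_base_accuracy(
            ovs, {"r1": 10_000, "r2": 10_000, "r3": 10_000}, 10_000)
        assert alpha == pytest.approx(0.99)
        assert eps == pytest.approx(0.01)

    def test_symmetric_identities_average(self):
        ovs = [ov(id1="r1", id2="r2", si=0.98),
               ov(id1="r3", id2="r4", si=1.00)]
        alpha, _ = estimate_base_accuracy(
            ovs, {f"r{i}": 10_000 for i in range(1, 5)}, 40_000)
        assert alpha == pytest.approx(0.99)

    def test_depth_cap_matches_brute_force(self):
        # r0 has three overlaps; at depth 2 only the top two by OS count
        partners = [("p1", 0.99, 9000), ("p2", 0.98, 8000), ("p3", 0.90, 7000)]
        ovs = [ov(id1="r0", id2=p, si=si, ol1=ol, ol2=ol)
               for p, si, ol in partners]
        read_lengths = {"r0": 20_000}
        alpha, _ = estimate_base_accuracy(ovs, read_lengths, 10_000)  # d=2
        ranked = sorted(ovs, key=lambda o: -overlap_score(o))[:2]
        assert alpha == pytest.approx(sum(o.si for o in ranked) / 2)

    def test_no_overlaps_is_error(self):
        with pytest.raises(ValueError):
            estimate_base_accuracy([], {"r1": 10_000}, 10_000)


def test_invalid_overlap_fields_rejected():
    with pytest.raises(ValueError):
        ov(ol1=0)
    with pytest.raises(ValueError):
        ov(si=1.5)
    with pytest.raises(ValueError):
        ov(id2="a")  # self overlap
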