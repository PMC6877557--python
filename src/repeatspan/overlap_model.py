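"""End-aware overlaps and their scores.

An alignment between two sequences is interpreted geometrically: which end
of each sequence it engages, how much unaligned sequence sits between the
aligned span and that end (the overhang OH — evidence of divergence, e.g.
a junction read anchored on the wrong repeat copy), and how far each
sequence protrudes past the other (the extension length EL — sequence
available to grow a tiling path).

Scores follow the method's definitions: the overlap score of a pair is
``OS = (OL1 + OL2) * SI / 2`` and the extension score of S2 extending S1 is
``ES2 = OS + EL2/2 - (OH1 + OH2)/2``, so overhangs on either side penalise
an extension while protruding sequence rewards it. Between a contig and a
read the extension score is always that of the read extending the contig.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .io_formats import PafRecord

HEAD = "head"
TAIL = "tail"
BOTH = "both"
NONE = "none"

DOVETAIL = "dovetail"
CONTAINED_1 = "contained_1"  # seq1 fully covered by seq2
CONTAINED_2 = "contained_2"
INTERNAL = "internal"        # alignment engages the middle of one sequence
PARTIAL = "partial"          # same-side end pairing; not usable for extension


@dataclass
class Params:
    """Tunable thresholds. Defaults are the values used genome-wide by the
    method's published runs; see docs/methods.md for units and rationale."""

    si_min: float = 0.97              # minimum overlap identity kept
    l_se: int = 25_000                # sequence-end window, bp
    l_me: int = 800_000               # maximum assembled-path length, bp
    ci_max: float = 0.75              # conflict-index threshold
    anchor_min_len: int = 50_000      # contigs at least this long anchor
    internal_read_identity: float = 0.995  # interior-read discard threshold
    contained_coverage: float = 0.995      # read-in-read containment threshold
    window_bp: int = 1_000            # path-length histogram window
    valley_ratio: float = 0.90        # valley/peak frequency ratio to split
    group_small_range_bp: int = 10_000  # spans within this range -> one group
    mutual_coverage: float = 0.95     # consensus validity: coverage per side
    complex_spread_bp: int = 100_000  # unsplittable spread beyond -> complex
    rw_trials: int = 200              # random-walk trials per anchor end
    backtrack_budget: int = 50        # backtracks per greedy first-step branch
    end_frac_cap: float = 0.25        # end window also capped at this fraction
    consensus_max_seqs: int = 40      # distinct sequences aligned per group
    gap_fill_max_dev: float = 0.50    # |span-gap|/gap cap for known-length fill
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.si_min <= 1.0):
            raise ValueError("si_min must lie in [0,1]")
        if not (0.0 <= self.ci_max <= 1.0):
            raise ValueError("ci_max must lie in [0,1]")
        if self.l_se >= self.l_me:
            raise ValueError("l_se must be smaller than l_me")
        for name in ("valley_ratio", "mutual_coverage", "internal_read_identity",
                     "contained_coverage"):
            v = getattr(self, name)
            if not (0.0 < v <= 1.0):
                raise ValueError(f"{name} must lie in (0,1]")

    def end_window(self, seq_len: int) -> float:
        """Bp from a sequence end still counting as that end.

        The fractional cap keeps short reads from being 'all end'.
        """
        return min(self.l_se, self.end_frac_cap * seq_len)


@dataclass(frozen=True)
class Overlap:
    """A scored pairwise alignment with per-end geometry.

    ``end1``/``end2`` name the engaged end of each sequence (``head``,
    ``tail``, ``both`` for a contained sequence, ``none`` for an interior
    alignment). OL/OH/EL are in bp on the respective sequence; EL is the
    protrusion of that sequence past the partner's engaged end.
    """

    id1: str
    id2: str
    end1: str
    end2: str
    strand: str
    ol1: int
    ol2: int
    si: float
    oh1: int = 0
    oh2: int = 0
    el1: int = 0
    el2: int = 0
    len1: int = 0
    len2: int = 0
    kind: str = DOVETAIL

    def __post_init__(self):
        if self.id1 == self.id2:
            raise ValueError("self-overlap")
        if self.ol1 <= 0 or self.ol2 <= 0:
            raise ValueError("overlap lengths must be positive")
        if not (0.0 <= self.si <= 1.0):
            raise ValueError("SI must lie in [0,1]")
        if min(self.oh1, self.oh2, self.el1, self.el2) < 0:
            raise ValueError("overhangs and extensions must be non-negative")

    # --- per-sequence accessors -------------------------------------------
    def other(self, seq_id: str) -> str:
        if seq_id == self.id1:
            return self.id2
        if seq_id == self.id2:
            return self.id1
        raise KeyError(seq_id)

    def end_of(self, seq_id: str) -> str:
        return self.end1 if seq_id == self.id1 else self.end2

    def ol_of(self, seq_id: str) -> int:
        return self.ol1 if seq_id == self.id1 else self.ol2

    def oh_of(self, seq_id: str) -> int:
        return self.oh1 if seq_id == self.id1 else self.oh2

    def el_of(self, seq_id: str) -> int:
        return self.el1 if seq_id == self.id1 else self.el2

    def len_of(self, seq_id: str) -> int:
        return self.len1 if seq_id == self.id1 else self.len2

    def key(self) -> tuple:
        return tuple(sorted(((self.id1, self.end1), (self.id2, self.end2))))


def overlap_score(ov: Overlap) -> float:
    """OS = (OL1 + OL2) * SI / 2 — symmetric in the two sequences."""
    return (ov.ol1 + ov.ol2) * ov.si / 2.0


def extension_score(ov: Overlap, extending: str) -> float:
    """ES of ``extending`` growing the other sequence:
    OS + EL_ext/2 - (OH1 + OH2)/2. Not symmetric."""
    return overlap_score(ov) + ov.el_of(extending) / 2.0 - (ov.oh1 + ov.oh2) / 2.0


def _engagement(left: int, right: int, win: float, coverage: float,
                contained_cov: float) -> str:
    """Which end of a sequence an alignment engages.

    A sequence counts as contained (``both``) only when the alignment
    covers nearly all of it; a partially covered sequence that still
    protrudes can extend its partner, so it engages the end with the
    smaller unaligned flank.
    """
    if coverage >= contained_cov:
        return BOTH
    lh = left < win
    rh = right < win
    if lh and rh:
        return HEAD if left <= right else TAIL
    if lh:
        return HEAD
    if rh:
        return TAIL
    return NONE


def _flip(end: str) -> str:
    if end == HEAD:
        return TAIL
    if end == TAIL:
        return HEAD
    return end


def overlap_from_paf(rec: PafRecord, seq_lens: Mapping[str, int],
                     params: Params) -> Overlap | None:
    """Interpret one PAF record as an end-aware overlap.

    Returns ``None`` when the alignment engages no end of either sequence
    within the end window (an interior repeat match, not an overlap).
    For strand '-' the target axis is mirrored before end assignment and
    the target's engaged end mapped back afterwards.
    """
    for sid, ln in ((rec.query_id, rec.query_len), (rec.target_id, rec.target_len)):
        if sid not in seq_lens:
            raise KeyError(f"sequence {sid!r} absent from collection")
        if seq_lens[sid] != ln:
            raise ValueError(f"PAF length {ln} for {sid!r} disagrees with "
                             f"sequence length {seq_lens[sid]}")
    if rec.query_id == rec.target_id:
        return None  # self-alignment carries no adjacency information

    lq = rec.query_start
    rq = rec.query_len - rec.query_end
    if rec.strand == "+":
        lt = rec.target_start
        rt = rec.target_len - rec.target_end
    else:  # mirror target so the two sequences are colinear
        lt = rec.target_len - rec.target_end
        rt = rec.target_start

    ol1 = rec.query_end - rec.query_start
    ol2 = rec.target_end - rec.target_start
    wq = params.end_window(rec.query_len)
    wt = params.end_window(rec.target_len)
    eq = _engagement(lq, rq, wq, ol1 / rec.query_len,
                     params.contained_coverage)
    et = _engagement(lt, rt, wt, ol2 / rec.target_len,
                     params.contained_coverage)

    if eq == NONE and et == NONE:
        return None

    si = rec.residue_matches / rec.block_len
    oh1 = oh2 = el1 = el2 = 0
    if (eq, et) == (TAIL, HEAD):       # query left of target
        oh1, oh2 = rq, lt
        el1, el2 = max(0, lq - lt), max(0, rt - rq)
        kind = DOVETAIL
    elif (eq, et) == (HEAD, TAIL):     # target left of query
        oh1, oh2 = lq, rt
        el1, el2 = max(0, rq - rt), max(0, lt - lq)
        kind = DOVETAIL
    elif eq == BOTH:
        kind = CONTAINED_1
    elif et == BOTH:
        kind = CONTAINED_2
    elif NONE in (eq, et):
        kind = INTERNAL
    else:                              # head/head or tail/tail pairing
        kind = PARTIAL

    if rec.strand == "-":
        et = _flip(et)

    return Overlap(id1=rec.query_id, id2=rec.target_id, end1=eq, end2=et,
                   strand=rec.strand, ol1=ol1, ol2=ol2, si=si,
                   oh1=oh1, oh2=oh2, el1=el1, el2=el2,
                   len1=rec.query_len, len2=rec.target_len, kind=kind)


def filter_overlaps(overlaps: Iterable[Overlap], read_ids: set[str],
                    contig_ids: set[str], params: Params
                    ) -> tuple[list[Overlap], set[str]]:
    """Apply the reduced-graph filters.

    Discards (a) overlaps below the identity cutoff, (b) every overlap of a
    read aligned to the interior of a contig with coverage and identity
    above the interior threshold, and (c) every overlap of a read fully
    contained in another read. Returns the surviving dovetail overlaps and
    the ids of discarded reads. Idempotent.
    """
    overlaps = list(overlaps)
    discarded: set[str] = set()

    for ov in overlaps:
        # (b) read covered by a contig interior at high identity
        for rid, cid, kind, cend in ((ov.id1, ov.id2, CONTAINED_1, ov.end2),
                                     (ov.id2, ov.id1, CONTAINED_2, ov.end1)):
            if (ov.kind == kind and rid in read_ids and cid in contig_ids
                    and cend == NONE):
                cov = ov.ol_of(rid) / ov.len_of(rid)
                if (cov > params.internal_read_identity
                        and ov.si > params.internal_read_identity):
                    discarded.add(rid)
        # (c) read contained in another read that represents it (a
        # low-identity cross-copy hit does not make a read redundant)
        for rid, oid, kind in ((ov.id1, ov.id2, CONTAINED_1),
                               (ov.id2, ov.id1, CONTAINED_2)):
            if (ov.kind == kind and rid in read_ids and oid in read_ids
                    and ov.si >= params.si_min):
                cov = ov.ol_of(rid) / ov.len_of(rid)
                if cov > params.contained_coverage:
                    discarded.add(rid)

    kept = [ov for ov in overlaps
            if ov.kind == DOVETAIL
            and ov.si >= params.si_min
            and ov.id1 not in discarded and ov.id2 not in discarded]
    return kept, discarded


def estimate_base_accuracy(overlaps: Iterable[Overlap],
                           read_lengths: Mapping[str, int],
                           genome_len_hint: int) -> tuple[float, float]:
    """Estimate mean read base accuracy alpha (and error rate 1 - alpha).

    For every read, its overlaps are ranked by overlap score and at most
    ``d = floor(total read bases / genome length)`` of them kept, so deep
    repeat pile-ups do not dominate; alpha is the mean identity of the kept
    overlaps. Ties break on (SI desc, partner id asc) for determinism.
    """
    if genome_len_hint <= 0:
        raise ValueError("genome_len_hint must be positive")
    per_read: dict[str, list[Overlap]] = {}
    n = 0
    for ov in overlaps:
        n += 1
        for sid in (ov.id1, ov.id2):
            if sid in read_lengths:
                per_read.setdefault(sid, []).append(ov)
    if n == 0:
        raise ValueError("no overlaps to estimate base accuracy from")

    depth = max(1, math.floor(sum(read_lengths.values()) / genome_len_hint))
    sis: list[float] = []
    for rid, ovs in per_read.items():
        ovs = sorted(ovs, key=lambda o: (-overlap_score(o), -o.si, o.other(rid)))
        sis.extend(o.si for o in ovs[:depth])
    if not sis:
        raise ValueError("no read overlaps to estimate base accuracy from")
    alpha = sum(sis) / len(sis)
    return alpha, 1.0 - alpha


def dump_overlaps(overlaps: Iterable[Overlap], path: str) -> None:
    """Write an audit table of overlaps (tab-separated)."""
    with open(path, "w") as fh:
        fh.write("id1\tend1\tid2\tend2\tstrand\tkind\tOL1\tOL2\tSI\t"
                 "OH1\tOH2\tEL1\tEL2\tOS\n")
        for ov in overlaps:
            fh.write("\t".join(str(x) for x in (
                ov.id1, ov.end1, ov.id2, ov.end2, ov.strand, ov.kind,
                ov.ol1, ov.ol2, f"{ov.si:.4f}", ov.oh1, ov.oh2,
                ov.el1, ov.el2, f"{overlap_score(ov):.1f}")) + "\n")
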