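"""Ground-truthed synthetic fixtures.

Generates genomes tiled from unique sequence, segmental-duplication pairs
at a requested identity and tandem arrays; long reads with a lognormal
length distribution and mixed substitution/indel errors; contigs
fragmented the way an assembler fragments them (unique stretches,
truncated a little inside each flanking repeat, with the repeats
themselves withheld); and a ground-truth adjacency table for chimera
auditing.

A self-contained minimizer-seeded overlap detector produces the
all-vs-all PAF so the whole pipeline runs without an external aligner.
It is a fixture/test oracle at desk scale, not a production aligner:
real inputs come with PAF from minimap2 or similar.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field
from typing import Sequence

import edlib
import numpy as np
from scipy.ndimage import minimum_filter1d

from .io_formats import PafRecord, SequenceRecord, revcomp

_BASES = "ACGT"


@dataclass(frozen=True)
class Feature:
    kind: str           # unique | repeat | copy | tandem
    start: int
    end: int
    name: str | None = None
    identity: float | None = None   # identity to mate (copy) / between units
    unit_len: int | None = None
    copies: int | None = None


@dataclass
class SyntheticTruth:
    genome: SequenceRecord
    features: list[Feature]
    contig_truth: list[tuple[str, int, int]] = field(default_factory=list)
    adjacency: set[tuple[str, str]] = field(default_factory=set)


def _random_seq(rng: random.Random, length: int) -> str:
    return "".join(rng.choices(_BASES, k=length))


def _mutate(seq: str, identity: float, rng: random.Random) -> str:
    """Apply point mutations and small indels to reach ~(1-identity)
    edits per base (80% substitutions, 10% 1-bp insertions, 10% deletions)."""
    n = round((1.0 - identity) * len(seq))
    if n == 0:
        return seq
    pos = sorted(rng.sample(range(len(seq)), n))
    out = []
    prev = 0
    for p in pos:
        out.append(seq[prev:p])
        r = rng.random()
        if r < 0.8:  # substitution
            out.append(rng.choice([b for b in _BASES if b != seq[p]]))
        elif r < 0.9:  # insertion (original base kept)
            out.append(seq[p])
            out.append(rng.choice(_BASES))
        # else deletion: emit nothing
        prev = p + 1
    out.append(seq[prev:])
    return "".join(out)


def simulate_genome(spec: Sequence[tuple], rng: random.Random,
                    genome_id: str = "genome") -> SyntheticTruth:
    """Build a genome from an ordered feature specification.

    Spec entries: ``("unique", length)``; ``("repeat", name, length)``
    places a fresh repeat and remembers it; ``("copy", name, identity)``
    re-emits a mutated copy of a remembered repeat; ``("tandem",
    unit_len, copies, identity)`` places an array of near-identical units.
    """
    parts: list[str] = []
    features: list[Feature] = []
    bank: dict[str, str] = {}
    cursor = 0
    for entry in spec:
        kind = entry[0]
        if kind == "unique":
            _, length = entry
            if length <= 0:
                raise ValueError("unique length must be positive")
            seq = _random_seq(rng, length)
            features.append(Feature("unique", cursor, cursor + len(seq)))
        elif kind == "repeat":
            _, name, length = entry
            if length <= 0:
                raise ValueError("repeat length must be positive")
            seq = _random_seq(rng, length)
            bank[name] = seq
            features.append(Feature("repeat", cursor, cursor + len(seq),
                                    name=name))
        elif kind == "copy":
            _, name, identity = entry
            if name not in bank:
                raise ValueError(f"copy of unknown repeat {name!r}")
            if not (0.90 <= identity <= 1.0):
                raise ValueError("copy identity must lie in [0.90, 1.0]")
            seq = _mutate(bank[name], identity, rng)
            features.append(Feature("copy", cursor, cursor + len(seq),
                                    name=name, identity=identity))
        elif kind == "tandem":
            _, unit_len, copies, identity = entry
            if unit_len <= 0 or copies < 2:
                raise ValueError("tandem needs unit_len > 0 and copies >= 2")
            if not (0.90 <= identity <= 1.0):
                raise ValueError("tandem identity must lie in [0.90, 1.0]")
            unit = _random_seq(rng, unit_len)
            units = [unit] + [_mutate(unit, identity, rng)
                              for _ in range(copies - 1)]
            seq = "".join(units)
            features.append(Feature("tandem", cursor, cursor + len(seq),
                                    identity=identity, unit_len=unit_len,
                                    copies=copies))
        else:
            raise ValueError(f"unknown feature kind {kind!r}")
        parts.append(seq)
        cursor += len(seq)
    if not parts:
        raise ValueError("empty genome specification")
    return SyntheticTruth(SequenceRecord(genome_id, "".join(parts)), features)


def simulate_reads(truth: SyntheticTruth, depth: float, mean_len: int,
                   err_rate: float, rng: random.Random,
                   min_len: int = 1_000, sigma: float = 0.3
                   ) -> list[SequenceRecord]:
    """Sample reads uniformly with lognormal lengths and mixed errors.

    Errors are substitutions:insertions:deletions at 2:1:1. Total read
    bases land within a few percent of ``depth * genome_length``. Output
    is byte-identical for a fixed rng state. Read ids encode the true
    interval and strand (``r00001_s100_e9100_f``).
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    if not (0.0 <= err_rate <= 0.05):
        raise ValueError("err_rate must lie in [0, 0.05]")
    genome = truth.genome.bases
    g = len(genome)
    target = depth * g
    mu = math.log(mean_len) - sigma ** 2 / 2
    np_rng = np.random.default_rng(rng.randrange(2 ** 31))
    reads: list[SequenceRecord] = []
    total = 0
    i = 0
    while total < target:
        length = min(g, max(min_len, round(rng.lognormvariate(mu, sigma))))
        start = rng.randrange(0, g - length + 1)
        frag = genome[start:start + length]
        fwd = rng.random() < 0.5
        if not fwd:
            frag = revcomp(frag)
        if err_rate > 0:
            frag = _apply_read_errors(frag, err_rate, np_rng)
        i += 1
        rid = f"r{i:05d}_s{start}_e{start + length}_{'f' if fwd else 'r'}"
        reads.append(SequenceRecord(rid, frag))
        total += len(frag)
    return reads


def _apply_read_errors(seq: str, err_rate: float,
                       np_rng: np.random.Generator) -> str:
    n = int(np_rng.binomial(len(seq), err_rate))
    if n == 0:
        return seq
    pos = np.sort(np_rng.choice(len(seq), size=n, replace=False))
    kinds = np_rng.random(n)
    subs = np_rng.integers(0, 3, size=n)
    ins = np_rng.integers(0, 4, size=n)
    out = []
    prev = 0
    for p, kind, s, b in zip(pos.tolist(), kinds.tolist(), subs.tolist(),
                             ins.tolist()):
        out.append(seq[prev:p])
        if kind < 0.5:   # substitution to a different base
            cur = _BASES.index(seq[p]) if seq[p] in _BASES else 0
            out.append(_BASES[(cur + 1 + s) % 4])
        elif kind < 0.75:  # insertion
            out.append(seq[p])
            out.append(_BASES[b])
        # else deletion
        prev = p + 1
    out.append(seq[prev:])
    return "".join(out)


def fragment_into_contigs(truth: SyntheticTruth, into_repeat: int = 5_000
                          ) -> list[SequenceRecord]:
    """Emit unique stretches as contigs, extended a little into each
    flanking repeat; the repeats themselves are withheld (the gaps to be
    assembled). Records contig intervals and true adjacency on ``truth``."""
    repeats = [f for f in truth.features if f.kind in ("repeat", "copy",
                                                       "tandem")]
    if not repeats:
        raise ValueError("genome has no repeat features to fragment at")
    genome = truth.genome.bases
    uniques = [f for f in truth.features if f.kind == "unique"]
    contigs: list[SequenceRecord] = []
    truth.contig_truth = []
    truth.adjacency = set()
    prev_id = None
    for idx, f in enumerate(uniques):
        left = next((r for r in repeats if r.end == f.start), None)
        right = next((r for r in repeats if r.start == f.end), None)
        cs = f.start - (min(into_repeat, (left.end - left.start) // 3)
                        if left else 0)
        ce = f.end + (min(into_repeat, (right.end - right.start) // 3)
                      if right else 0)
        cid = f"ctg{idx + 1:02d}"
        contigs.append(SequenceRecord(cid, genome[cs:ce]))
        truth.contig_truth.append((cid, cs, ce))
        if prev_id is not None:
            truth.adjacency.add((prev_id, cid))
        prev_id = cid
    return contigs


def true_adjacent(truth: SyntheticTruth, a: str, b: str) -> bool:
    return (a, b) in truth.adjacency or (b, a) in truth.adjacency


# ---------------------------------------------------------------------------
# minimizer-seeded overlap detection (fixture oracle)

_LUT = np.zeros(256, dtype=np.int64)
for _i, _b in enumerate(_BASES):
    _LUT[ord(_b)] = _i

_MIX = np.uint64(0x9E3779B97F4A7C15)
# hashes stay below 2**52 so the float64-based window-minimum filter
# compares them exactly
_MASK = np.uint64((1 << 52) - 1)


def _minimizers(seq: str, k: int, w: int
                ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Window-minimum canonical k-mer hashes: (hash, position, strand)."""
    n = len(seq)
    if n < k:
        return (np.empty(0, np.int64),) * 3
    code = _LUT[np.frombuffer(seq.encode(), dtype=np.uint8)]
    m = n - k + 1
    kf = np.zeros(m, dtype=np.uint64)
    kr = np.zeros(m, dtype=np.uint64)
    rc = (3 - code)[::-1]
    for i in range(k):
        kf = (kf << np.uint64(2)) | code[i:i + m].astype(np.uint64)
        kr = (kr << np.uint64(2)) | rc[i:i + m].astype(np.uint64)
    kr = kr[::-1]  # align rc k-mer hashes to forward positions
    hf = ((kf * _MIX) & _MASK).astype(np.int64)
    hr = ((kr * _MIX) & _MASK).astype(np.int64)
    canon = np.minimum(hf, hr)
    strand = (hr < hf).astype(np.int8)
    if m <= w:
        sel = np.array([int(np.argmin(canon))])
    else:
        wmin = minimum_filter1d(canon, size=w, mode="nearest")
        sel = np.flatnonzero(canon == wmin)
    return canon[sel], sel.astype(np.int64), strand[sel]


def naive_overlap_detect(seqs: Sequence[SequenceRecord],
                         min_len: int = 1_000, min_si: float = 0.90,
                         k: int = 15, w: int = 19, max_occ: int = 300,
                         min_chain: int = 3, band: int = 300,
                         max_pairs: int = 5_000_000) -> list[PafRecord]:
    """All-vs-all overlap detection by shared minimizers + verification.

    Shared window-minimum k-mer hashes vote for (pair, strand, diagonal)
    candidates; each candidate's implied dovetail/containment region is
    verified with a global edlib alignment, yielding exact match counts.
    When the input is large the pairing stage subsamples the hash space,
    which loses only very short overlaps. Emits one record per retained
    alignment with the lower-index sequence as query.
    """
    names = [s.id for s in seqs]
    lens = np.array([s.length for s in seqs], dtype=np.int64)
    all_h, all_p, all_s, all_i = [], [], [], []
    for idx, s in enumerate(seqs):
        h, p, st = _minimizers(s.bases, k, w)
        all_h.append(h)
        all_p.append(p)
        all_s.append(st)
        all_i.append(np.full(len(h), idx, dtype=np.int64))
    H = np.concatenate(all_h)
    if len(H) == 0:
        return []
    order0 = np.argsort(H, kind="stable")
    H = H[order0]
    P = np.concatenate(all_p)[order0]
    S = np.concatenate(all_s).astype(np.int64)[order0]
    I = np.concatenate(all_i)[order0]

    # subsample hash space until the pair-generation workload is bounded
    f = 1
    while True:
        m = (H % f == 0) if f > 1 else np.ones(len(H), dtype=bool)
        h = H[m]
        if len(h) == 0:
            return []
        starts = np.flatnonzero(np.r_[True, h[1:] != h[:-1]])
        sizes = np.diff(np.r_[starts, len(h)])
        est = int((sizes[sizes <= max_occ].astype(np.int64) ** 2).sum())
        if est <= max_pairs or f >= 1 << 20:
            break
        f *= 2
    p = P[m]
    s = S[m]
    i = I[m]

    qs_l, ts_l, rel_l, dg_l = [], [], [], []
    good = (sizes >= 2) & (sizes <= max_occ)
    for g0, sz in zip(starts[good].tolist(), sizes[good].tolist()):
        sl = slice(g0, g0 + sz)
        gi, gp, gs = i[sl], p[sl], s[sl]
        a = np.repeat(np.arange(sz), sz)
        b = np.tile(np.arange(sz), sz)
        keep = gi[a] < gi[b]
        a, b = a[keep], b[keep]
        if len(a) == 0:
            continue
        qs_l.append(gi[a])
        ts_l.append(gi[b])
        rel = (gs[a] != gs[b]).astype(np.int64)
        rel_l.append(rel)
        tp_fwd = gp[b]
        tp_rc = lens[gi[b]] - k - gp[b]
        dg_l.append(gp[a] - np.where(rel == 0, tp_fwd, tp_rc))
    if not qs_l:
        return []
    Q = np.concatenate(qs_l)
    T = np.concatenate(ts_l)
    R = np.concatenate(rel_l)
    D = np.concatenate(dg_l)

    key = (Q * len(seqs) + T) * 2 + R
    order = np.lexsort((D, key))
    key, Q, T, R, D = key[order], Q[order], T[order], R[order], D[order]
    # cluster boundaries: new pair/orientation, or a distinct diagonal
    # (tandem units align the same pair at several unit-spaced offsets)
    cut = np.r_[True, (key[1:] != key[:-1]) | (np.diff(D) > band)]
    cl_start = np.flatnonzero(cut)
    cl_size = np.diff(np.r_[cl_start, len(key)])
    good2 = cl_size >= min_chain
    cl_start, cl_size = cl_start[good2], cl_size[good2]
    lens_l = lens.tolist()

    rc_cache: dict[int, str] = {}
    records: list[PafRecord] = []
    emitted: set[tuple] = set()
    for g0, sz in zip(cl_start.tolist(), cl_size.tolist()):
        qi = int(Q[g0])
        ti = int(T[g0])
        rel = int(R[g0])
        diag = int(D[g0 + sz // 2])  # median: diagonals sorted within cluster
        lq, lt = lens_l[qi], lens_l[ti]
        a0 = max(0, diag)
        b0 = max(0, -diag)
        L = min(lq - a0, lt - b0)
        if L < min_len:
            continue
        sig = (qi, ti, rel, a0 // band, b0 // band)
        if sig in emitted:
            continue
        emitted.add(sig)
        qsub = seqs[qi].bases[a0:a0 + L]
        if rel == 0:
            tsub = seqs[ti].bases[b0:b0 + L]
        else:
            if ti not in rc_cache:
                rc_cache[ti] = revcomp(seqs[ti].bases)
            tsub = rc_cache[ti][b0:b0 + L]
        cap = int((1.0 - min_si) * L) + 1
        dist = edlib.align(qsub, tsub, mode="NW", task="distance",
                           k=cap)["editDistance"]
        if dist < 0:
            continue  # provably below the identity floor
        si = 1.0 - dist / L
        if si < min_si:
            continue
        if rel == 0:
            t_lo, t_hi = b0, b0 + L
        else:
            t_lo, t_hi = lt - (b0 + L), lt - b0
        records.append(PafRecord(
            query_id=names[qi], query_len=lq,
            query_start=a0, query_end=a0 + L,
            strand="+" if rel == 0 else "-",
            target_id=names[ti], target_len=lt,
            target_start=t_lo, target_end=t_hi,
            residue_matches=L - dist, block_len=L, mapq=60))
    return records


# ---------------------------------------------------------------------------
# ready-made fixtures

@dataclass
class Fixture:
    truth: SyntheticTruth
    contigs: list[SequenceRecord]
    reads: list[SequenceRecord]
    paf: list[PafRecord]


def make_segdup_fixture(seed: int,
                        unique_lens: tuple[int, int, int, int] = (
                            70_000, 60_000, 60_000, 70_000),
                        repeat_len: int = 30_000,
                        spacer_len: int = 25_000,
                        identity: float = 0.97,
                        depth: float = 30.0,
                        mean_read: int = 9_000,
                        err_rate: float = 0.01,
                        into_repeat: int = 5_000) -> Fixture:
    """Genome U1-R-U2-Q-U3-R'-U4: one segmental-duplication pair (R, R')
    in separate gaps, plus an unrelated withheld spacer region Q whose
    gap is unique sequence. Four anchor ends face the repeat copies;
    near-identical copies put all four in conflict."""
    rng = random.Random(seed)
    spec = [("unique", unique_lens[0]), ("repeat", "R", repeat_len),
            ("unique", unique_lens[1]), ("repeat", "Q", spacer_len),
            ("unique", unique_lens[2]), ("copy", "R", identity),
            ("unique", unique_lens[3])]
    truth = simulate_genome(spec, rng)
    contigs = fragment_into_contigs(truth, into_repeat=into_repeat)
    reads = simulate_reads(truth, depth, mean_read, err_rate, rng)
    paf = naive_overlap_detect(list(contigs) + reads)
    return Fixture(truth, contigs, reads, paf)


def make_tandem_fixture(seed: int,
                        flank_len: int = 80_000,
                        unit_len: int = 20_000,
                        copies: int = 3,
                        unit_identity: float = 0.999,
                        depth: float = 30.0,
                        mean_read: int = 9_000,
                        err_rate: float = 0.005,
                        into_repeat: int = 0) -> Fixture:
    """Genome U1-[unit x copies]-U2 with near-identical tandem units."""
    rng = random.Random(seed)
    spec = [("unique", flank_len), ("tandem", unit_len, copies, unit_identity),
            ("unique", flank_len)]
    truth = simulate_genome(spec, rng)
    contigs = fragment_into_contigs(truth, into_repeat=into_repeat)
    reads = simulate_reads(truth, depth, mean_read, err_rate, rng)
    paf = naive_overlap_detect(list(contigs) + reads)
    return Fixture(truth, contigs, reads, paf)
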