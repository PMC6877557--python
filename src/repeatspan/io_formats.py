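"""Readers and writers for the plain-text formats the tool touches.

FASTA carries contigs (anchoring sequences) and corrected long reads; PAF
carries the all-vs-all alignments produced by an external aligner such as
minimap2; AGP v2.1 records how each assembled super-contig is composed of
contig and fill components. Two small tab-separated tables carry optional
scaffold gap lengths and contig grouping/order constraints.

PAF is the single alignment ingestion dialect (0-based half-open
coordinates); SAM/BAM users convert upstream.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Iterable, Sequence

from Bio.SeqIO.FastaIO import SimpleFastaParser

_VALID_BASES = frozenset("ACGTN")

_RC = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of an uppercase nucleotide string."""
    return seq.translate(_RC)[::-1]


@dataclass(frozen=True)
class SequenceRecord:
    """A named nucleotide sequence (contig or corrected read)."""

    id: str
    bases: str

    def __post_init__(self):
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        if not self.bases:
            raise ValueError(f"sequence {self.id!r} is empty")

    @property
    def length(self) -> int:
        return len(self.bases)


@dataclass(frozen=True)
class PafRecord:
    """One line of minimap2-style PAF (12 mandatory columns).

    Coordinates are 0-based half-open on the forward strand of both
    sequences; for strand '-' the query aligns to the reverse complement
    of the target interval.
    """

    query_id: str
    query_len: int
    query_start: int
    query_end: int
    strand: str
    target_id: str
    target_len: int
    target_start: int
    target_end: int
    residue_matches: int
    block_len: int
    mapq: int

    def __post_init__(self):
        for side, lo, hi, ln in (
            ("query", self.query_start, self.query_end, self.query_len),
            ("target", self.target_start, self.target_end, self.target_len),
        ):
            if not (0 <= lo < hi <= ln):
                raise ValueError(
                    f"invalid {side} interval [{lo},{hi}) for length {ln} "
                    f"({self.query_id} vs {self.target_id})"
                )
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")
        if self.residue_matches > self.block_len:
            raise ValueError("residue_matches exceeds block_len")


def read_fasta(path: str | os.PathLike) -> list[SequenceRecord]:
    """Load a (possibly line-wrapped) FASTA file, uppercasing sequences.

    Duplicate ids and empty sequences are errors; record order is preserved.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    with open(path) as fh:
        for header, seq in SimpleFastaParser(fh):
            name = header.split()[0] if header.split() else ""
            if name in seen:
                raise ValueError(f"duplicate sequence id {name!r} in {path}")
            seq = seq.upper()
            bad = set(seq) - _VALID_BASES
            if bad:
                raise ValueError(
                    f"sequence {name!r} contains invalid characters {sorted(bad)}"
                )
            seen.add(name)
            records.append(SequenceRecord(name, seq))
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | os.PathLike,
                width: int = 80) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.bases), width):
                fh.write(rec.bases[i:i + width] + "\n")


def parse_paf(path: str | os.PathLike) -> list[PafRecord]:
    """Parse a PAF file, keeping the 12 core columns and ignoring tags."""
    records: list[PafRecord] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise ValueError(f"{path}:{ln}: PAF needs >=12 columns, "
                                 f"got {len(fields)}")
            records.append(PafRecord(
                query_id=fields[0], query_len=int(fields[1]),
                query_start=int(fields[2]), query_end=int(fields[3]),
                strand=fields[4],
                target_id=fields[5], target_len=int(fields[6]),
                target_start=int(fields[7]), target_end=int(fields[8]),
                residue_matches=int(fields[9]), block_len=int(fields[10]),
                mapq=int(fields[11]),
            ))
    return records


def write_paf(records: Iterable[PafRecord], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write("\t".join(str(x) for x in (
                r.query_id, r.query_len, r.query_start, r.query_end, r.strand,
                r.target_id, r.target_len, r.target_start, r.target_end,
                r.residue_matches, r.block_len, r.mapq)) + "\n")


@dataclass(frozen=True)
class AgpComponent:
    """One W line of an AGP object: a contig or fill span.

    ``object_beg``/``object_end`` are 0-based half-open here; they are
    converted to AGP's 1-based inclusive convention on write.
    """

    object_id: str
    object_beg: int
    object_end: int
    component_id: str
    component_beg: int
    component_end: int
    orientation: str = "+"


def write_agp(components: Sequence[AgpComponent], path: str | os.PathLike) -> None:
    """Write AGP v2.1. Components must tile each object contiguously."""
    by_obj: dict[str, list[AgpComponent]] = {}
    for c in components:
        by_obj.setdefault(c.object_id, []).append(c)
    with open(path, "w") as fh:
        fh.write("##agp-version\t2.1\n")
        for obj, comps in by_obj.items():
            comps = sorted(comps, key=lambda c: c.object_beg)
            cursor = 0
            for part, c in enumerate(comps, 1):
                if c.object_beg != cursor:
                    raise ValueError(
                        f"{obj}: component {c.component_id} starts at "
                        f"{c.object_beg}, expected {cursor} (not contiguous)")
                if c.object_end <= c.object_beg:
                    raise ValueError(f"{obj}: empty component {c.component_id}")
                span = c.object_end - c.object_beg
                if c.component_end - c.component_beg != span:
                    raise ValueError(
                        f"{obj}: component {c.component_id} span mismatch")
                fh.write("\t".join(str(x) for x in (
                    obj, c.object_beg + 1, c.object_end, part, "W",
                    c.component_id, c.component_beg + 1, c.component_end,
                    c.orientation)) + "\n")
                cursor = c.object_end


def read_gap_table(path: str | os.PathLike) -> list[tuple[str, str, str, int]]:
    """Read ``scaffold_id  left_contig  right_contig  gap_len_bp`` rows."""
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise ValueError(f"{path}:{ln}: gap table needs 4 columns")
            gap = int(fields[3])
            if gap < 0:
                raise ValueError(f"{path}:{ln}: negative gap length")
            rows.append((fields[0], fields[1], fields[2], gap))
    return rows


def read_group_table(path: str | os.PathLike) -> dict[str, tuple[str, int, str]]:
    """Read ``contig_id  group_id  order_index  orientation`` constraints."""
    table: dict[str, tuple[str, int, str]] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise ValueError(f"{path}:{ln}: group table needs 4 columns")
            cid, gid, order, orient = fields
            if orient not in ("+", "-", "?"):
                raise ValueError(f"{path}:{ln}: bad orientation {orient!r}")
            if cid in table:
                raise ValueError(f"{path}:{ln}: duplicate contig {cid!r}")
            table[cid] = (gid, int(order), orient)
    return table
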