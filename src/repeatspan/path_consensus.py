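"""Grouping tiling paths by length and choosing a representative.

Paths between the same pair of anchor ends differ in length when the gap
contains tandemly repeated units: walks that hop between near-identical
units produce path populations at roughly unit-length spacings. The path
lengths are therefore histogrammed in fixed windows; qualifying valleys
between peaks split the population into groups, one consensus path is
chosen per group by mutual alignment, and one group is finally selected —
by proximity to a known gap length when there is one, otherwise by an
iterative shorter-versus-longer count comparison. Populations that spread
widely without separable peaks mark a complex repeat and yield no
connection at all.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import edlib

from .io_formats import revcomp
from .overlap_graph import HEAD
from .overlap_model import Params
from .path_search import PROV_DIRECT, TilingPath, path_score


@dataclass
class PathGroup:
    """A cluster of similar-length paths with its consensus representative.

    ``np`` is the high-scoring path number: how many member paths validly
    match the consensus sequence (the consensus itself included). It is
    the edge weight of the connection graph.
    """

    paths: list[TilingPath]
    span_min: int
    span_max: int
    consensus: TilingPath | None = None
    np: int = 0
    peak_freq: int = 0
    consensus_seq: str | None = None

    @property
    def consensus_span(self) -> int | None:
        return None if self.consensus is None else self.consensus.span_len


def splice_path_sequence(path: TilingPath, seqs: Mapping[str, str]) -> str:
    """Materialise the fill sequence between the two anchor bodies.

    Each read contributes its protruding suffix (reverse-complemented when
    entered tail-first); the final read's portion overlapping the target
    anchor is trimmed off. For an error-free path the result is exactly
    the genomic substring between the anchors, and its length equals
    ``span_len``.
    """
    if path.provenance == PROV_DIRECT or not path.steps:
        return ""
    parts: list[str] = []
    for entry, ov in zip(path.steps, path.overlaps):
        bases = seqs[entry.node_id]
        el = ov.el_of(entry.node_id)
        if el > len(bases):
            raise ValueError(
                f"overlap extension {el} exceeds read length for {entry.node_id}")
        oriented = bases if entry.end == HEAD else revcomp(bases)
        parts.append(oriented[len(oriented) - el:])
    fov = path.overlaps[-1]
    last = path.steps[-1].node_id
    trim = fov.oh_of(last) + fov.ol_of(last) + fov.oh_of(path.target.node_id)
    s = "".join(parts)
    return s[:max(0, len(s) - trim)]


def _bin_counts(spans: Sequence[int], window_bp: int) -> tuple[list[int], int]:
    lo = min(spans)
    nbins = (max(spans) - lo) // window_bp + 1
    counts = [0] * nbins
    for s in spans:
        counts[(s - lo) // window_bp] += 1
    return counts, lo


def _local_maxima(counts: Sequence[int]) -> list[int]:
    peaks = []
    n = len(counts)
    for i in range(n):
        left = counts[i - 1] if i > 0 else -1
        right = counts[i + 1] if i < n - 1 else -1
        if counts[i] >= left and counts[i] >= right and counts[i] > 0:
            peaks.append(i)
    return peaks


def group_paths_by_length(paths: Sequence[TilingPath], params: Params
                          ) -> list[PathGroup]:
    """Split paths into length groups at qualifying histogram valleys.

    All paths form one group when their spans lie within a small range.
    Otherwise spans are histogrammed in fixed windows anchored at the
    minimum span; between each pair of neighbouring peaks, the lowest
    valley window splits the set iff its count falls below the valley
    ratio of the right peak's count. The valley window itself joins the
    left group; the leftmost lowest window wins ties.
    """
    if not paths:
        raise ValueError("no paths to group")
    spans = [p.span_len for p in paths]
    if max(spans) - min(spans) < params.group_small_range_bp:
        return [PathGroup(list(paths), min(spans), max(spans))]

    counts, lo = _bin_counts(spans, params.window_bp)
    peaks = _local_maxima(counts)
    boundaries: list[int] = []
    for p1, p2 in zip(peaks, peaks[1:]):
        if p2 - p1 < 2:
            continue
        region = counts[p1 + 1:p2]
        vmin = min(region)
        v = p1 + 1 + region.index(vmin)  # leftmost lowest valley window
        if vmin < params.valley_ratio * counts[p2]:
            boundaries.append(v)

    if not boundaries:
        return [PathGroup(list(paths), min(spans), max(spans))]

    members: dict[int, list[TilingPath]] = {}
    for p in paths:
        b = (p.span_len - lo) // params.window_bp
        gi = sum(1 for v in boundaries if b > v)
        members.setdefault(gi, []).append(p)
    groups = []
    for gi in sorted(members):
        gp = members[gi]
        gs = [p.span_len for p in gp]
        groups.append(PathGroup(gp, min(gs), max(gs)))
    return groups


def _global_identity(a: str, b: str, floor: float) -> float:
    """Global identity, or 0.0 if it provably falls below ``floor``
    (the banded search gives up past the implied edit-distance cap)."""
    if not a and not b:
        return 1.0
    if not a or not b:
        return 0.0
    cap = int((1.0 - floor) * max(len(a), len(b))) + 1
    dist = edlib.align(a, b, mode="NW", task="distance",
                       k=cap)["editDistance"]
    if dist < 0:
        return 0.0
    return 1.0 - dist / max(len(a), len(b))


def select_consensus_in_group(group: PathGroup, seqs: Mapping[str, str],
                              params: Params, seq_fn=None) -> PathGroup:
    """Pick the group's consensus path and count its support.

    Paths in windows with fewer than half the modal window count are
    discarded; the remaining paths' spliced sequences are aligned all
    against all (duplicate read chains counted by multiplicity without
    re-alignment), a pair being a valid match when each sequence is
    covered to the mutual-coverage floor at acceptable identity. The
    consensus is a modal-window path matching the most others; ``np``
    counts the paths matching it, itself included.

    ``seq_fn`` overrides how a path is turned into a comparable sequence
    (used to orient paths searched from opposite ends consistently).
    """
    if seq_fn is None:
        seq_fn = lambda p: splice_path_sequence(p, seqs)  # noqa: E731
    if not group.paths:
        raise ValueError("empty path group")
    spans = [p.span_len for p in group.paths]
    counts, lo = _bin_counts(spans, params.window_bp)
    modal = max(counts)
    freq = {id(p): counts[(p.span_len - lo) // params.window_bp]
            for p in group.paths}
    kept = [p for p in group.paths if 2 * freq[id(p)] >= modal]
    if not kept:
        raise ValueError("group emptied by the frequency filter")

    chains: dict[tuple, list[TilingPath]] = {}
    for p in kept:
        chains.setdefault(p.chain_key(), []).append(p)
    order = sorted(chains,
                   key=lambda k: (-freq[id(chains[k][0])], -len(chains[k]), k))
    aligned = order[:params.consensus_max_seqs]
    seq_of = {k: seq_fn(chains[k][0]) for k in aligned}

    match_count: dict[tuple, int] = {}
    valid: dict[tuple[tuple, tuple], bool] = {}
    for i, ka in enumerate(aligned):
        total = len(chains[ka])  # identical chains always match
        for j, kb in enumerate(aligned):
            if i == j:
                continue
            pair = (ka, kb) if ka <= kb else (kb, ka)
            if pair not in valid:
                a, b = seq_of[ka], seq_of[kb]
                if min(len(a), len(b)) < params.mutual_coverage * max(len(a), len(b)):
                    ok = False
                elif not a and not b:
                    ok = True
                else:
                    ok = _global_identity(a, b, params.si_min) >= params.si_min
                valid[pair] = ok
            if valid[pair]:
                total += len(chains[kb])
        match_count[ka] = total

    candidates = [k for k in aligned if freq[id(chains[k][0])] == modal]
    if not candidates:  # modal chains beyond the alignment cap
        candidates = aligned

    def tie_key(k):
        rep = chains[k][0]
        return (-match_count[k], -path_score(rep), rep.span_len, rep.read_ids)

    best = min(candidates, key=tie_key)
    group.consensus = chains[best][0]
    group.np = match_count[best]
    group.peak_freq = modal
    group.consensus_seq = seq_of[best]
    return group


def select_group(groups: Sequence[PathGroup], known_gap_len: int | None,
                 params: Params) -> PathGroup:
    """Choose one length group as the connection between an anchor pair.

    With a known gap length the group whose consensus span lies nearest
    wins. Otherwise, starting from the group with the highest window
    frequency, the count comparison walks toward longer groups: exactly
    two groups always yield the longer one; with more, the longer group
    advances while its path count exceeds half the current one's.
    """
    groups = [g for g in groups if g.consensus is not None]
    if not groups:
        raise ValueError("no groups with consensus to select from")
    groups = sorted(groups, key=lambda g: g.consensus_span)

    if known_gap_len is not None:
        return min(groups, key=lambda g: (abs(g.consensus_span - known_gap_len),
                                          -g.np))

    if len(groups) == 2:
        return groups[1]
    start = min(range(len(groups)),
                key=lambda i: (-groups[i].peak_freq, groups[i].consensus_span))
    cur = groups[start]
    for g in groups[start + 1:]:
        if g.np > cur.np / 2:
            cur = g
        else:
            break
    return cur


def detect_complex_repeat(paths: Sequence[TilingPath], params: Params) -> bool:
    """True when the paths spread widely in length yet cannot be split
    into separate groups — the signature of a complex repeat, which by
    default contributes no connection."""
    if not paths:
        return False
    groups = group_paths_by_length(paths, params)
    spread = max(p.span_len for p in paths) - min(p.span_len for p in paths)
    return len(groups) == 1 and spread > params.complex_spread_bp
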