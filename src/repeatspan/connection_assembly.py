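"""Connection graph, conflict resolution and super-contig assembly.

The connection graph keeps only the anchoring nodes; an edge between two
anchor ends carries the number of high-scoring paths supporting that
connection (NP, summed over both search directions) and the consensus
fill sequence. Near-identical repeat copies produce two incident edges of
similar NP at an end; the conflict index CI = NP_second / NP_max flags
such ends, and an end with CI above the threshold is never joined unless
the conflict resolves — committing a competitor's confident connection
elsewhere removes the competing edge and can release the end.
"""

from __future__ import annotations

import logging
import random
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .io_formats import AgpComponent, SequenceRecord, revcomp
from .overlap_graph import (HEAD, TAIL, NodeEnd, OverlapGraph,
                            assign_read_anchor_links, build_overlap_graph,
                            classify_sequences)
from .overlap_model import (Overlap, Params, estimate_base_accuracy,
                            filter_overlaps, overlap_from_paf)
from .path_consensus import (PathGroup, detect_complex_repeat,
                             group_paths_by_length, select_consensus_in_group,
                             select_group, splice_path_sequence)
from .path_search import PROV_DIRECT, TilingPath, collect_paths, rng_for_end

logger = logging.getLogger(__name__)


@dataclass
class ConnectionEdge:
    """An undirected anchor-end pair with its pooled path support."""

    end_a: NodeEnd
    end_b: NodeEnd
    np: int
    consensus_seq: str
    consensus_span: int
    consensus_from: NodeEnd  # direction whose consensus was adopted
    cons_path: TilingPath | None = None

    def key(self) -> tuple[NodeEnd, NodeEnd]:
        return tuple(sorted((self.end_a, self.end_b)))

    @property
    def direct(self) -> bool:
        return (self.cons_path is not None
                and self.cons_path.provenance == PROV_DIRECT)

    @property
    def self_anchor(self) -> bool:
        return self.end_a.node_id == self.end_b.node_id

    def other_end(self, end: NodeEnd) -> NodeEnd:
        return self.end_b if end == self.end_a else self.end_a


@dataclass
class ConflictState:
    end: NodeEnd
    np_max: int
    np_second: int

    @property
    def ci(self) -> float:
        """Second-largest over largest incident NP; 0 with <2 edges."""
        return self.np_second / self.np_max if self.np_max > 0 else 0.0

    def conflicting(self, params: Params) -> bool:
        return self.ci > params.ci_max


@dataclass
class ConnectionGraph:
    edges: dict[tuple, ConnectionEdge] = field(default_factory=dict)

    def add(self, edge: ConnectionEdge) -> None:
        self.edges[edge.key()] = edge

    def incident(self, end: NodeEnd) -> list[ConnectionEdge]:
        return [e for e in self.edges.values()
                if end in (e.end_a, e.end_b)]

    def ends(self) -> list[NodeEnd]:
        out = set()
        for e in self.edges.values():
            out.add(e.end_a)
            out.add(e.end_b)
        return sorted(out)


def build_connection_graph(
        directional: Mapping[tuple[NodeEnd, NodeEnd], PathGroup]
) -> ConnectionGraph:
    """Merge per-direction chosen groups into undirected edges.

    NP is the sum of both directions' high-scoring path numbers; the
    consensus comes from the direction with the larger count (ties break
    on the lexicographically smaller source end). Directions whose
    consensus spans disagree grossly mark an unreliable pair and the edge
    is dropped with a warning.
    """
    cg = ConnectionGraph()
    merged: dict[tuple, list[tuple[NodeEnd, NodeEnd, PathGroup]]] = {}
    for (src, dst), group in directional.items():
        if group.consensus is None:
            raise ValueError("directional group lacks a consensus")
        merged.setdefault(tuple(sorted((src, dst))), []).append((src, dst, group))

    for key, entries in merged.items():
        entries = sorted(entries, key=lambda t: (-t[2].np, t[0]))
        src, dst, lead = entries[0]
        np_total = sum(g.np for _, _, g in entries)
        if len(entries) == 2:
            spans = [g.consensus_span for _, _, g in entries]
            if abs(spans[0] - spans[1]) > 10_000:
                logger.warning(
                    "dropping inconsistent connection %s: directional "
                    "consensus spans %s disagree", key, spans)
                continue
        cg.add(ConnectionEdge(
            end_a=key[0], end_b=key[1], np=np_total,
            consensus_seq=lead.consensus_seq or "",
            consensus_span=lead.consensus_span,
            consensus_from=src, cons_path=lead.consensus))
    return cg


def conflict_index(cg: ConnectionGraph, end: NodeEnd) -> ConflictState:
    nps = sorted((e.np for e in cg.incident(end)), reverse=True)
    if not nps:
        return ConflictState(end, 0, 0)
    if len(nps) == 1:
        return ConflictState(end, nps[0], 0)
    return ConflictState(end, nps[0], nps[1])


@dataclass
class ResolutionResult:
    committed: list[ConnectionEdge]
    states: dict[NodeEnd, ConflictState]      # CI at the start of resolution
    report: list[tuple]                       # (end_a, end_b, NP, status)


def _apply_constraints(cg: ConnectionGraph,
                       constraints: Mapping[str, tuple[str, int, str]] | None,
                       report: list) -> dict[tuple, ConnectionEdge]:
    edges = dict(cg.edges)
    if not constraints:
        return edges
    anchor_ids = {e.node_id for e in cg.ends()}
    unknown = set(constraints) - anchor_ids
    if unknown:
        raise ValueError(f"constraint table references unknown contigs: "
                         f"{sorted(unknown)}")
    for key, e in list(edges.items()):
        c1 = constraints.get(e.end_a.node_id)
        c2 = constraints.get(e.end_b.node_id)
        if c1 is None or c2 is None:
            continue
        veto = c1[0] != c2[0] or abs(c1[1] - c2[1]) != 1
        if veto:
            report.append((e.end_a, e.end_b, e.np, "vetoed"))
            del edges[key]
    return edges


def resolve_conflicts(cg: ConnectionGraph, params: Params,
                      constraints: Mapping[str, tuple[str, int, str]] | None = None
                      ) -> ResolutionResult:
    """Iteratively commit connections, most confident first.

    Each round recomputes per-end conflict indices on the surviving edges
    and looks for mutual-best pairs (each end's largest-NP edge points at
    the other). Pairs whose both ends are non-conflicting commit first;
    when none exist, the highest-NP mutual-best pair with at least one
    non-conflicting end commits — the still-conflicted partner is being
    claimed by its most confident connection, and the commitment deletes
    its competing edges, which can release other ends in later rounds.
    Ends still conflicting when no committable pair remains stay unjoined.
    """
    report: list[tuple] = []
    edges = _apply_constraints(cg, constraints, report)
    initial_states = {end: conflict_index(cg, end) for end in cg.ends()}
    committed: list[ConnectionEdge] = []

    def incident(end):
        return [e for e in edges.values() if end in (e.end_a, e.end_b)]

    while True:
        ends = set()
        for e in edges.values():
            ends.add(e.end_a)
            ends.add(e.end_b)
        best: dict[NodeEnd, ConnectionEdge] = {}
        ci: dict[NodeEnd, float] = {}
        for end in ends:
            inc = sorted(incident(end), key=lambda e: (-e.np, e.key()))
            best[end] = inc[0]
            ci[end] = inc[1].np / inc[0].np if len(inc) > 1 else 0.0

        mutual = []
        for key, e in edges.items():
            if e.self_anchor:
                continue  # a contig is never joined to itself
            if best.get(e.end_a) is e and best.get(e.end_b) is e:
                mutual.append(e)
        tier1 = [e for e in mutual
                 if ci[e.end_a] <= params.ci_max and ci[e.end_b] <= params.ci_max]
        pool = tier1 if tier1 else [
            e for e in mutual
            if ci[e.end_a] <= params.ci_max or ci[e.end_b] <= params.ci_max]
        if not pool:
            break
        chosen = sorted(pool, key=lambda e: (-e.np, e.key()))[0]
        committed.append(chosen)
        report.append((chosen.end_a, chosen.end_b, chosen.np, "committed"))
        del edges[chosen.key()]
        for end in (chosen.end_a, chosen.end_b):
            for e in incident(end):
                report.append((e.end_a, e.end_b, e.np, "pruned"))
                del edges[e.key()]

    for e in edges.values():
        report.append((e.end_a, e.end_b, e.np, "conflicted"))
    return ResolutionResult(committed, initial_states, report)


def assemble_super_contigs(cg: ConnectionGraph,
                           committed: Sequence[ConnectionEdge],
                           contigs: Mapping[str, SequenceRecord]
                           ) -> tuple[list[SequenceRecord], list[AgpComponent],
                                      list[SequenceRecord]]:
    """Concatenate anchors and consensus fills into super-contigs.

    Committed links must form a matching on anchor ends. Chains alternate
    contig bodies and fills; a contig entered through its tail is
    reverse-complemented. Cycles are broken at their minimum-NP edge.
    Direct contig-contig joins (empty fill) trim the downstream contig by
    the overlap length so no sequence is duplicated.
    """
    partner: dict[NodeEnd, ConnectionEdge] = {}
    for e in committed:
        for end in (e.end_a, e.end_b):
            if end in partner:
                raise ValueError(f"anchor end {end} committed to two partners")
            partner[end] = e

    # break cycles (components where every anchor has both ends linked)
    # at their minimum-NP edge
    adj: dict[str, list[ConnectionEdge]] = {}
    for e in {e.key(): e for e in committed}.values():
        adj.setdefault(e.end_a.node_id, []).append(e)
        adj.setdefault(e.end_b.node_id, []).append(e)
    seen_comp: set[str] = set()
    for aid in sorted(adj):
        if aid in seen_comp:
            continue
        comp: set[str] = set()
        stack = [aid]
        while stack:
            x = stack.pop()
            if x in comp:
                continue
            comp.add(x)
            for e in adj.get(x, []):
                stack.append(e.end_a.node_id)
                stack.append(e.end_b.node_id)
        seen_comp |= comp
        if all(NodeEnd(x, HEAD) in partner and NodeEnd(x, TAIL) in partner
               for x in comp):
            comp_edges = {e.key(): e for x in comp for e in adj[x]}
            weakest = min(comp_edges.values(), key=lambda x: (x.np, x.key()))
            del partner[weakest.end_a]
            del partner[weakest.end_b]

    supers: list[SequenceRecord] = []
    components: list[AgpComponent] = []
    fills: list[SequenceRecord] = []
    done: set[str] = set()
    n_super = n_fill = 0

    def chain_start(aid: str) -> tuple[str, str]:
        """Walk to the leftmost anchor of aid's chain; return it with its
        orientation (committed end facing right)."""
        cur, cur_or = aid, None
        if NodeEnd(aid, TAIL) in partner:
            cur_or = "+"
        elif NodeEnd(aid, HEAD) in partner:
            cur_or = "-"
        else:
            return aid, "+"
        # step leftwards while the left-facing end is linked
        while True:
            left_end = NodeEnd(cur, HEAD if cur_or == "+" else TAIL)
            if left_end not in partner:
                return cur, cur_or
            edge = partner[left_end]
            prev_end = edge.other_end(left_end)
            cur = prev_end.node_id
            cur_or = "+" if prev_end.end == TAIL else "-"

    for aid in sorted(contigs):
        if aid in done:
            continue
        start, orient = chain_start(aid)
        n_super += 1
        obj = f"super_{n_super:04d}"
        parts: list[str] = []
        cursor = 0
        part_trim = 0  # leading trim of the contig about to be placed
        cur, cur_or = start, orient
        while True:
            rec = contigs[cur]
            done.add(cur)
            seq = rec.bases if cur_or == "+" else revcomp(rec.bases)
            seq = seq[part_trim:]
            if cur_or == "+":
                cbeg, cend = part_trim, rec.length
            else:
                cbeg, cend = 0, rec.length - part_trim
            components.append(AgpComponent(obj, cursor, cursor + len(seq),
                                           rec.id, cbeg, cend, cur_or))
            parts.append(seq)
            cursor += len(seq)
            out_end = NodeEnd(cur, TAIL if cur_or == "+" else HEAD)
            if out_end not in partner:
                break
            edge = partner[out_end]
            nxt_end = edge.other_end(out_end)
            fill = edge.consensus_seq
            if fill and edge.consensus_from != out_end:
                fill = revcomp(fill)
            part_trim = 0
            if edge.direct:
                ov: Overlap = edge.cons_path.overlaps[0]
                part_trim = ov.ol_of(nxt_end.node_id)
            if fill:
                n_fill += 1
                fid = f"fill_{n_fill:04d}"
                fills.append(SequenceRecord(fid, fill))
                components.append(AgpComponent(obj, cursor, cursor + len(fill),
                                               fid, 0, len(fill), "+"))
                parts.append(fill)
                cursor += len(fill)
            cur = nxt_end.node_id
            cur_or = "+" if nxt_end.end == HEAD else "-"
        supers.append(SequenceRecord(obj, "".join(parts)))
    return supers, components, fills


def fill_gap(graph: OverlapGraph, left_end: NodeEnd, right_end: NodeEnd,
             gap_len: int, params: Params,
             seqs: Mapping[str, str]) -> str | None:
    """Assemble a gap of known length between two anchor ends.

    Runs a targeted path search from the left end, keeps only paths
    reaching the right end, groups them by length and selects the group
    whose consensus span is closest to the gap length. Returns ``None``
    when no path exists or the best span deviates from the gap length by
    more than the configured fraction.
    """
    if left_end == right_end:
        raise ValueError("gap flanks must be distinct anchor ends")
    if gap_len < 0:
        raise ValueError("gap length must be non-negative")
    grouped = collect_paths(graph, left_end, params)
    paths = grouped.get(right_end)
    if not paths:
        return None
    groups = group_paths_by_length(paths, params)
    for g in groups:
        select_consensus_in_group(g, seqs, params)
    chosen = select_group(groups, gap_len, params)
    if abs(chosen.consensus_span - gap_len) > params.gap_fill_max_dev * max(gap_len, 1):
        return None
    return chosen.consensus_seq


# ---------------------------------------------------------------------------
# end-to-end pipeline

@dataclass
class AssemblyResult:
    super_contigs: list[SequenceRecord]
    components: list[AgpComponent]
    fills: list[SequenceRecord]
    resolution: ResolutionResult
    connection_graph: ConnectionGraph
    graph: OverlapGraph
    alpha: float | None
    complex_pairs: list[tuple[NodeEnd, NodeEnd]]


def connect_contigs(contigs: Sequence[SequenceRecord],
                    reads: Sequence[SequenceRecord],
                    paf_records: Iterable,
                    params: Params,
                    constraints: Mapping[str, tuple[str, int, str]] | None = None
                    ) -> AssemblyResult:
    """Run the whole pipeline: overlaps -> graph -> paths -> connections ->
    conflict resolution -> super-contigs."""
    anchors, demoted = classify_sequences(contigs, params)
    read_pool = list(reads) + demoted
    for r in read_pool:
        if "N" in r.bases:
            raise ValueError(f"read {r.id!r} contains N (corrected reads "
                             "must be fully called)")
    seq_lens = {s.id: s.length for s in list(contigs) + list(reads)}
    seqs = {s.id: s.bases for s in list(contigs) + list(reads)}

    overlaps = []
    for rec in paf_records:
        ov = overlap_from_paf(rec, seq_lens, params)
        if ov is not None:
            overlaps.append(ov)
    read_ids = {r.id for r in read_pool}
    anchor_ids = {a.id for a in anchors}
    kept, discarded = filter_overlaps(overlaps, read_ids, anchor_ids, params)

    alpha = None
    read_lens = {r.id: r.length for r in read_pool if r.id not in discarded}
    genome_hint = sum(a.length for a in anchors)
    try:
        alpha, _ = estimate_base_accuracy(kept, read_lens, genome_hint)
    except ValueError:
        pass

    graph = build_overlap_graph(
        anchors, [r for r in read_pool if r.id not in discarded], kept, params)
    assign_read_anchor_links(graph, random.Random(params.seed))

    # pool the paths found from both ends of every anchor-end pair before
    # grouping, so the pair gets one consistent length decision and NP
    # counts the supporting paths from both search directions
    pair_paths: dict[tuple[NodeEnd, NodeEnd], list[tuple[TilingPath, bool]]] = {}
    for aid in sorted(graph.anchors):
        for end in (NodeEnd(aid, HEAD), NodeEnd(aid, TAIL)):
            for target, paths in sorted(collect_paths(graph, end, params).items()):
                key = tuple(sorted((end, target)))
                fwd = end == key[0]
                pair_paths.setdefault(key, []).extend((p, fwd) for p in paths)

    directional: dict[tuple[NodeEnd, NodeEnd], PathGroup] = {}
    complex_pairs: list[tuple[NodeEnd, NodeEnd]] = []
    for key, pw in sorted(pair_paths.items()):
        paths = [p for p, _ in pw]
        if detect_complex_repeat(paths, params):
            complex_pairs.append(key)
            continue
        fwdness = {p.chain_key(): fwd for p, fwd in pw}

        def seq_fn(p, _fwdness=fwdness):
            s = splice_path_sequence(p, seqs)
            return s if _fwdness[p.chain_key()] else revcomp(s)

        groups = group_paths_by_length(paths, params)
        for g in groups:
            select_consensus_in_group(g, seqs, params, seq_fn=seq_fn)
        directional[key] = select_group(groups, None, params)

    cg = build_connection_graph(directional)
    resolution = resolve_conflicts(cg, params, constraints)
    anchor_recs = {a.id: a for a in anchors}
    supers, components, fills = assemble_super_contigs(
        cg, resolution.committed, anchor_recs)
    return AssemblyResult(supers, components, fills, resolution, cg, graph,
                          alpha, complex_pairs)
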