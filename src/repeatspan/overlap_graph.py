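"""The two-ended undirected overlap graph.

Every sequence is a node with an explicit head and tail end, and edges
attach to *ends*, not nodes: entering a node through one end forces the
traversal to exit through the other, which is what makes a walk through
the graph a valid tiling path. Contigs at or above the anchor length
cutoff become anchoring nodes; shorter contigs are pooled with the reads
and behave exactly like them.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Iterable, Iterator, NamedTuple

from .io_formats import SequenceRecord
from .overlap_model import (DOVETAIL, HEAD, TAIL, Overlap, Params,
                            overlap_score)


class NodeEnd(NamedTuple):
    node_id: str
    end: str  # "head" or "tail"

    def mate(self) -> "NodeEnd":
        return NodeEnd(self.node_id, TAIL if self.end == HEAD else HEAD)


def classify_sequences(contigs: Iterable[SequenceRecord], params: Params
                       ) -> tuple[list[SequenceRecord], list[SequenceRecord]]:
    """Split contigs into anchors (>= anchor_min_len) and demoted short
    contigs that will be pooled with the reads."""
    contigs = list(contigs)
    if not contigs:
        raise ValueError("no contigs to classify")
    anchors = [c for c in contigs if c.length >= params.anchor_min_len]
    demoted = [c for c in contigs if c.length < params.anchor_min_len]
    if not anchors:
        raise ValueError(
            f"no contig reaches the anchor cutoff ({params.anchor_min_len} bp)")
    return anchors, demoted


@dataclass
class OverlapGraph:
    """Undirected overlap graph with per-end adjacency.

    ``anchors`` and ``reads`` map node ids to sequence lengths. Edges are
    stored symmetrically under both endpoint ends.
    """

    anchors: dict[str, int] = field(default_factory=dict)
    reads: dict[str, int] = field(default_factory=dict)
    _adj: dict[NodeEnd, dict[tuple, tuple[NodeEnd, Overlap]]] = field(
        default_factory=dict)

    # --- construction -----------------------------------------------------
    def add_edge(self, e1: NodeEnd, e2: NodeEnd, ov: Overlap) -> None:
        if e1.node_id == e2.node_id:
            raise ValueError("self-edge")
        for e in (e1, e2):
            if e.node_id not in self.anchors and e.node_id not in self.reads:
                raise KeyError(f"edge references unknown node {e.node_id!r}")
        key = ov.key()
        prev = self._adj.get(e1, {}).get(key)
        if prev is not None and overlap_score(prev[1]) >= overlap_score(ov):
            return  # keep the stronger of two alignments joining the same ends
        self._adj.setdefault(e1, {})[key] = (e2, ov)
        self._adj.setdefault(e2, {})[key] = (e1, ov)

    def remove_edge(self, e1: NodeEnd, e2: NodeEnd, ov: Overlap) -> None:
        key = ov.key()
        self._adj.get(e1, {}).pop(key, None)
        self._adj.get(e2, {}).pop(key, None)

    # --- queries ----------------------------------------------------------
    def is_anchor(self, node_id: str) -> bool:
        return node_id in self.anchors

    def edges_at(self, end: NodeEnd) -> list[tuple[NodeEnd, Overlap]]:
        """Neighbouring ends and overlaps incident on ``end``, in a
        deterministic order."""
        items = self._adj.get(end, {})
        return [items[k] for k in sorted(items)]

    def degree(self, end: NodeEnd) -> int:
        return len(self._adj.get(end, {}))

    def anchor_link(self, end: NodeEnd) -> tuple[NodeEnd, Overlap] | None:
        """The (at most one, after pruning) anchor neighbour of a read end."""
        links = [(other, ov) for other, ov in self.edges_at(end)
                 if self.is_anchor(other.node_id)]
        if not links:
            return None
        if len(links) > 1:
            raise AssertionError(f"read end {end} keeps {len(links)} anchor links")
        return links[0]

    def ends(self) -> Iterator[NodeEnd]:
        for nid in list(self.anchors) + list(self.reads):
            yield NodeEnd(nid, HEAD)
            yield NodeEnd(nid, TAIL)

    def n_edges(self) -> int:
        return sum(len(v) for v in self._adj.values()) // 2


def build_overlap_graph(anchors: Iterable[SequenceRecord],
                        reads: Iterable[SequenceRecord],
                        filtered_overlaps: Iterable[Overlap],
                        params: Params) -> OverlapGraph:
    """Assemble the graph from filtered dovetail overlaps.

    Anchor-anchor direct overlaps are retained (they indicate contigs that
    physically overlap) and can be recognised through ``is_anchor`` on both
    endpoints.
    """
    g = OverlapGraph(anchors={a.id: a.length for a in anchors},
                     reads={r.id: r.length for r in reads})
    for ov in filtered_overlaps:
        if ov.kind != DOVETAIL:
            continue
        e1 = NodeEnd(ov.id1, ov.end1)
        e2 = NodeEnd(ov.id2, ov.end2)
        g.add_edge(e1, e2, ov)
    return g


def assign_read_anchor_links(graph: OverlapGraph,
                             rng: random.Random | None = None) -> OverlapGraph:
    """Keep, per read end, only the single highest-overlap-score anchor edge.

    Equal scores are broken by a seeded random draw, as the method
    prescribes; read-read edges are never pruned.
    """
    rng = rng or random.Random(0)
    for rid in graph.reads:
        for end in (NodeEnd(rid, HEAD), NodeEnd(rid, TAIL)):
            anchor_edges = [(other, ov) for other, ov in graph.edges_at(end)
                            if graph.is_anchor(other.node_id)]
            if len(anchor_edges) <= 1:
                continue
            scored = sorted(anchor_edges,
                            key=lambda t: -overlap_score(t[1]))
            best_score = overlap_score(scored[0][1])
            tied = [t for t in scored
                    if overlap_score(t[1]) == best_score]
            keep = tied[rng.randrange(len(tied))] if len(tied) > 1 else scored[0]
            for other, ov in anchor_edges:
                if ov.key() != keep[1].key():
                    graph.remove_edge(end, other, ov)
    return graph


def dump_graph(graph: OverlapGraph, path: str) -> None:
    """Serialize the edge list for debugging."""
    seen = set()
    with open(path, "w") as fh:
        fh.write("node1\tend1\tnode2\tend2\tOL1\tOL2\tSI\tOS\n")
        for end in graph.ends():
            for other, ov in graph.edges_at(end):
                if ov.key() in seen:
                    continue
                seen.add(ov.key())
                fh.write("\t".join(str(x) for x in (
                    end.node_id, end.end, other.node_id, other.end,
                    ov.ol1, ov.ol2, f"{ov.si:.4f}",
                    f"{overlap_score(ov):.1f}")) + "\n")
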