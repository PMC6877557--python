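"""Tiling-path search between anchoring-node ends.

From each anchor end the graph is traversed read by read until a read is
reached whose far end holds a link to a different anchor, which closes the
path. Three complementary strategies are used and their results pooled:

* greedy extension by best overlap score, with backtracking on dead ends;
* greedy extension by best extension score, likewise;
* repeated random walks in which each step samples among the candidate
  reads with probability proportional to extension score.

Sequencing errors make any single best-scored path unreliable; the point
of generating many is that paths between truly adjacent anchors are far
more numerous than paths that stray across repeat copies, and downstream
stages count them.
"""

from __future__ import annotations

import random
import zlib
from dataclasses import dataclass
from typing import Iterable, Literal

from .overlap_graph import NodeEnd, OverlapGraph
from .overlap_model import Overlap, Params, extension_score, overlap_score

Mode = Literal["overlap_score", "extension_score"]

PROV_GREEDY_OVERLAP = "I"
PROV_GREEDY_EXTENSION = "II"
PROV_RANDOM_WALK = "III"
PROV_DIRECT = "direct"


@dataclass(frozen=True)
class TilingPath:
    """An ordered walk from one anchor end through reads to another anchor.

    ``steps`` holds each read's entry end in traversal order; ``overlaps``
    holds the anchor-read overlap, the read-read overlaps, and finally the
    read-anchor overlap that closes the path. ``span_len`` is the spliced
    length strictly between the two anchor bodies.
    """

    start: NodeEnd
    steps: tuple[NodeEnd, ...]
    overlaps: tuple[Overlap, ...]
    target: NodeEnd
    span_len: int
    provenance: str

    @property
    def read_ids(self) -> tuple[str, ...]:
        return tuple(s.node_id for s in self.steps)

    def chain_key(self) -> tuple:
        """Identity for de-duplication: the ordered read chain."""
        return (self.start, self.steps, self.target)


def path_score(path: TilingPath, mode: Mode = "overlap_score") -> float:
    """Average per-overlap score along the path.

    In extension mode each overlap is scored as the entering sequence
    extending the previous one; for a read meeting an anchor that is
    always the read extending the anchor.
    """
    if not path.overlaps:
        raise ValueError("path has no overlaps")
    if mode == "overlap_score" or path.provenance == PROV_DIRECT:
        scores = [overlap_score(ov) for ov in path.overlaps]
    else:
        extenders = [s.node_id for s in path.steps]
        if len(path.overlaps) == len(path.steps) + 1:
            extenders = extenders + [path.steps[-1].node_id]
        scores = [extension_score(ov, ext)
                  for ov, ext in zip(path.overlaps, extenders)]
    return sum(scores) / len(scores)


def _span_len(tip: int, final_ov: Overlap, read_id: str, anchor_id: str) -> int:
    # distance from the start anchor's end to the target anchor's engaged end
    return max(0, tip - final_ov.oh_of(read_id) - final_ov.ol_of(read_id)
               - final_ov.oh_of(anchor_id))


def _candidates(graph: OverlapGraph, at_end: NodeEnd, used: set[str]
                ) -> list[tuple[NodeEnd, Overlap]]:
    """Unused read ends reachable from ``at_end`` that genuinely extend it."""
    out = []
    for other, ov in graph.edges_at(at_end):
        if graph.is_anchor(other.node_id) or other.node_id in used:
            continue
        if ov.el_of(other.node_id) > 0:
            out.append((other, ov))
    return out


def _terminal(graph: OverlapGraph, entry: NodeEnd, start_anchor: str
              ) -> tuple[NodeEnd, Overlap] | None:
    """Anchor link on the read's far end, if it points to another anchor."""
    link = graph.anchor_link(entry.mate())
    if link is not None and link[0].node_id != start_anchor:
        return link
    return None


def _rank_key(ov: Overlap, read: NodeEnd, graph: OverlapGraph, mode: Mode,
              rng: random.Random):
    score = (overlap_score(ov) if mode == "overlap_score"
             else extension_score(ov, read.node_id))
    length = graph.reads.get(read.node_id, 0)
    # score, then identity, then read length, then a seeded random tie-break
    return (-score, -ov.si, -length, rng.random())


def extend_path_fixed(graph: OverlapGraph, start_end: NodeEnd, mode: Mode,
                      params: Params, rng: random.Random | None = None
                      ) -> list[TilingPath]:
    """Greedy depth-first extension with backtracking.

    Every read on the start anchor end seeds its own branch; afterwards
    only the top-ranked unused candidate is followed, falling back to the
    next-ranked on dead ends (bounded by the backtrack budget). A branch
    closes as soon as a read linking to a different anchor is entered, or
    is abandoned past the maximum path length.
    """
    if not graph.is_anchor(start_end.node_id):
        raise ValueError("path search must start at an anchor end")
    rng = rng or random.Random(params.seed)
    prov = (PROV_GREEDY_OVERLAP if mode == "overlap_score"
            else PROV_GREEDY_EXTENSION)
    results: list[TilingPath] = []

    first = sorted(_candidates(graph, start_end, set()),
                   key=lambda t: _rank_key(t[1], t[0], graph, mode, rng))
    for entry0, ov0 in first:
        path = _greedy_branch(graph, start_end, entry0, ov0, mode, params,
                              rng, prov)
        if path is not None:
            results.append(path)
    return results


def _greedy_branch(graph, start_end, entry0, ov0, mode, params, rng, prov):
    start_anchor = start_end.node_id
    # frame: (entry, overlap, tip_after, ranked candidate list, next index)
    tip0 = ov0.el_of(entry0.node_id)
    stack = [[entry0, ov0, tip0, None, 0]]
    used = {entry0.node_id}
    backtracks = 0

    while stack:
        frame = stack[-1]
        entry, ov, tip = frame[0], frame[1], frame[2]
        term = _terminal(graph, entry, start_anchor)
        if term is not None:
            target, fov = term
            steps = tuple(f[0] for f in stack)
            overlaps = tuple(f[1] for f in stack) + (fov,)
            span = _span_len(tip, fov, entry.node_id, target.node_id)
            return TilingPath(start_end, steps, overlaps, target, span, prov)
        if frame[3] is None:
            cands = _candidates(graph, entry.mate(), used)
            frame[3] = sorted(
                cands, key=lambda t: _rank_key(t[1], t[0], graph, mode, rng))
        advanced = False
        while frame[4] < len(frame[3]):
            nxt, nov = frame[3][frame[4]]
            frame[4] += 1
            if nxt.node_id in used:
                continue
            ntip = tip + nov.el_of(nxt.node_id)
            if ntip > params.l_me:
                continue
            stack.append([nxt, nov, ntip, None, 0])
            used.add(nxt.node_id)
            advanced = True
            break
        if not advanced:
            stack.pop()
            used.discard(entry.node_id)
            backtracks += 1
            if backtracks > params.backtrack_budget:
                return None
    return None


def sample_by_extension_score(rng: random.Random,
                              weights: Iterable[float]) -> int:
    """Sample an index with probability proportional to extension score.

    Extension scores can be negative when overhangs are large, so when any
    weight is non-positive all weights are shifted by (1 - min) first.
    """
    ws = list(weights)
    lo = min(ws)
    if lo <= 0:
        ws = [w - lo + 1.0 for w in ws]
    return rng.choices(range(len(ws)), weights=ws, k=1)[0]


def extend_paths_random_walk(graph: OverlapGraph, start_end: NodeEnd,
                             params: Params, rng: random.Random
                             ) -> list[TilingPath]:
    """Run ``rw_trials`` independent score-weighted walks from an anchor end.

    Each trial ends on reaching a read linked to another anchor (success)
    or on a dead end / length breach (failure); successful walks may repeat
    and are de-duplicated later.
    """
    if not graph.is_anchor(start_end.node_id):
        raise ValueError("path search must start at an anchor end")
    start_anchor = start_end.node_id
    paths: list[TilingPath] = []

    for _ in range(params.rw_trials):
        used: set[str] = set()
        steps: list[NodeEnd] = []
        overlaps: list[Overlap] = []
        tip = 0
        cur = start_end
        while True:
            if steps:
                term = _terminal(graph, steps[-1], start_anchor)
                if term is not None:
                    target, fov = term
                    span = _span_len(tip, fov, steps[-1].node_id,
                                     target.node_id)
                    paths.append(TilingPath(
                        start_end, tuple(steps), tuple(overlaps) + (fov,),
                        target, span, PROV_RANDOM_WALK))
                    break
            cands = [(e, ov) for e, ov in _candidates(graph, cur, used)
                     if tip + ov.el_of(e.node_id) <= params.l_me]
            if not cands:
                break  # failed trial
            ws = [extension_score(ov, e.node_id) for e, ov in cands]
            entry, ov = cands[sample_by_extension_score(rng, ws)]
            used.add(entry.node_id)
            steps.append(entry)
            overlaps.append(ov)
            tip += ov.el_of(entry.node_id)
            cur = entry.mate()
    return paths


def _direct_paths(graph: OverlapGraph, start_end: NodeEnd) -> list[TilingPath]:
    """Zero-read candidate connections from direct anchor-anchor overlaps."""
    out = []
    for other, ov in graph.edges_at(start_end):
        if graph.is_anchor(other.node_id):
            out.append(TilingPath(start_end, (), (ov,), other, 0, PROV_DIRECT))
    return out


def rng_for_end(params: Params, end: NodeEnd) -> random.Random:
    """One reproducible RNG stream per anchor end."""
    token = f"{params.seed}:{end.node_id}:{end.end}".encode()
    return random.Random(zlib.crc32(token))


def collect_paths(graph: OverlapGraph, start_end: NodeEnd, params: Params,
                  rng: random.Random | None = None
                  ) -> dict[NodeEnd, list[TilingPath]]:
    """Union of all three search strategies, de-duplicated by read chain
    and keyed by the anchor end each path reaches."""
    rng = rng or rng_for_end(params, start_end)
    pool: list[TilingPath] = []
    pool += extend_path_fixed(graph, start_end, "overlap_score", params, rng)
    pool += extend_path_fixed(graph, start_end, "extension_score", params, rng)
    pool += extend_paths_random_walk(graph, start_end, params, rng)
    pool += _direct_paths(graph, start_end)

    seen: set[tuple] = set()
    grouped: dict[NodeEnd, list[TilingPath]] = {}
    for p in pool:
        k = p.chain_key()
        if k in seen:
            continue
        seen.add(k)
        grouped.setdefault(p.target, []).append(p)
    return grouped
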