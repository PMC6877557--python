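"""Hand-buildable toy graphs and an independent path-search oracle."""

import random

from repeatspan.overlap_graph import HEAD, TAIL, NodeEnd, OverlapGraph
from repeatspan.overlap_model import Overlap, extension_score, overlap_score


def mk_ov(id1, end1, id2, end2, ol=5000, si=1.0, el1=1000, el2=1000,
          oh1=0, oh2=0, len1=10_000, len2=10_000):
    return Overlap(id1=id1, id2=id2, end1=end1, end2=end2, strand="+",
                   ol1=ol, ol2=ol, si=si, oh1=oh1, oh2=oh2, el1=el1, el2=el2,
                   len1=len1, len2=len2)


def toy_graph(edges, anchors=("A", "B"), read_len=10_000):
    """Build a two-ended graph from ((id1, end1, id2, end2, kwargs)) specs."""
    read_ids = sorted({i for e in edges for i in (e[0], e[2])
                       if i not in anchors})
    g = OverlapGraph(anchors={a: 60_000 for a in anchors},
                     reads={r: read_len for r in read_ids})
    for id1, end1, id2, end2, kw in edges:
        o = mk_ov(id1, end1, id2, end2, **kw)
        g.add_edge(NodeEnd(id1, end1), NodeEnd(id2, end2), o)
    return g


def random_toy_graph(rng: random.Random, n_reads: int):
    """Random searchable topology between anchors A and B with all-distinct
    overlap and extension scores (so greedy ranking has no ties)."""
    ols = rng.sample(range(2000, 9000), k=60)
    edges = []
    k = 0

    def kw():
        nonlocal k
        k += 1
        return dict(ol=ols[k - 1], el1=rng.randrange(500, 3000),
                    el2=rng.randrange(500, 3000))

    reads = [f"r{i}" for i in range(n_reads)]
    for r in rng.sample(reads, k=min(n_reads, rng.randrange(1, 4))):
        edges.append(("A", TAIL, r, HEAD, kw()))
    for _ in range(rng.randrange(n_reads, 3 * n_reads)):
        i, j = rng.sample(range(n_reads), 2)
        edges.append((reads[i], TAIL, reads[j], HEAD, kw()))
    for r in rng.sample(reads, k=min(n_reads, rng.randrange(1, 3))):
        edges.append((r, TAIL, "B", HEAD, kw()))
    return toy_graph(edges)


def oracle_greedy_paths(graph, start_end, mode):
    """Independent recursive greedy-with-backtracking enumeration.

    One path per first-step read: follow the top-scored unused candidate,
    falling back to the next on dead ends; stop on a read whose far end
    links a different anchor. Assumes all-distinct scores.
    """
    start_anchor = start_end.node_id

    def score(o, read_id):
        return (overlap_score(o) if mode == "overlap_score"
                else extension_score(o, read_id))

    def cands(at_end, used):
        out = [(e, o) for e, o in graph.edges_at(at_end)
               if not graph.is_anchor(e.node_id) and e.node_id not in used
               and o.el_of(e.node_id) > 0]
        return sorted(out, key=lambda t: -score(t[1], t[0].node_id))

    def explore(entry, used):
        link = graph.anchor_link(entry.mate())
        if link is not None and link[0].node_id != start_anchor:
            return ((entry,), link[0])
        for nxt, _ in cands(entry.mate(), used):
            got = explore(nxt, used | {nxt.node_id})
            if got is not None:
                chain, target = got
                return ((entry,) + chain, target)
        return None

    results = []
    for first, _ in cands(start_end, set()):
        got = explore(first, {first.node_id})
        if got is not None:
            results.append(got)
    return results
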