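# Methods

## Problem setting and model

The input is a set of pre-assembled contigs of unknown genomic order, a
set of self-corrected long reads, and all-vs-all pairwise alignments in
PAF. Two contigs are *adjacent* when no other contig lies between them
on the chromosome; the goal is to connect as many adjacent pairs as
possible by assembling the sequence between them, without ever joining
two non-adjacent contigs (a chimeric join). The central difficulty is
that the missing sequence is usually a repeat: reads from different
copies of a segmental duplication look alike up to the inter-copy
divergence plus twice the read error rate.

The method exploits two observations. First, read overlaps within one
repeat copy score systematically higher than overlaps across copies, so
a score-guided traversal tends to stay on the correct copy whenever the
copies are less similar than roughly the read accuracy. Second, because
sequencing errors are random, the *number* of distinct high-scoring
tiling paths between a truly adjacent pair exceeds the number between
non-adjacent pairs — counting paths is more robust than trusting any
single best-scoring path. When both signals fail (copies more than
~99.5% identical), the correct response is to leave the ends unjoined,
and the conflict index makes that veto explicit.

## Overlap geometry

A PAF record is interpreted on a common axis (the target axis is
mirrored for `-` strand alignments, and the target's engaged end mapped
back afterwards). Per side, the alignment's unaligned flanks decide
which end it engages; a flank shorter than `min(L_se, 0.25·len)` counts
as reaching that end. The fractional cap keeps short reads from being
"all end"; `L_se` is the sequence-end window of the model. A sequence
counts as *contained* only when the alignment covers ≥ 99.5% of it —
a mostly-covered sequence that still protrudes can extend its partner
and therefore engages the end with the smaller flank. This last rule is
load-bearing: treating every near-covered junction read as contained
would strip its anchor link and let traversals slip past contig ends
through the contig interior, which manifests as absurdly long paths and
spurious connections between distant anchors.

Identity is taken as `residue_matches / block_len` from the PAF record.
Overhangs (OH) are the unaligned flanks on the engaged sides; extension
lengths (EL) are each sequence's protrusion past the partner's engaged
end. Both are reported symmetrically for the two sequences; scores only
ever consume the extending side's EL, and between a contig and a read
the extension score is always that of the read extending the contig.

## Reduced-graph filters

Three filters shrink the graph before construction: (a) overlaps with
SI below `si_min` are dropped; (b) reads aligned to a contig interior
with coverage and identity above 99.5% are discarded entirely — they
are redundant with assembled sequence; (c) reads fully contained
(coverage > 99.5%) in another read *at acceptable identity* (≥ `si_min`)
are discarded as redundant. The identity condition in (c) matters in
repeat regions: a read from one copy can be "covered" by a cross-copy
alignment at 95% identity, and discarding it would thin true coverage
exactly where it is scarcest.

The mean read accuracy α is estimated as the average SI of surviving
overlaps, capping each read's contribution at the average depth
(total read bases / genome length, the anchor total by default) to keep
repeat pile-ups from dominating. With error-free reads α is exactly 1.

## Path search

Each anchor end seeds three searches. The two greedy modes branch on
every first-step read, then follow the single top-ranked unused
candidate (by OS or ES; ties by identity, then read length, then a
seeded coin), backtracking to the next-ranked candidate on dead ends.
Backtracking is budgeted (default 50 events per branch) so adversarial
topologies terminate. The random walk runs `rw_trials` (default 200)
independent trials, sampling candidates proportionally to ES; when any
candidate's ES is non-positive, all weights are shifted by `1 − min` so
the distribution stays valid. Every path stops at the first read whose
far end links a different anchor, never reuses a read, and is abandoned
past `L_me` (default 800 kb). One RNG stream is derived per anchor end
from the global seed, so results are reproducible and order-independent.

A read end may keep at most one anchor link — the highest-OS one, ties
broken by a seeded draw — which both caps the branching at anchors and
defines path termination. Direct contig–contig dovetail overlaps are
carried as zero-read candidate connections; when committed, the
downstream contig is trimmed by the overlap length in the AGP component
coordinates, so no base is written twice.

## Length grouping, consensus, NP

Paths found from *both* ends of a pair are pooled before grouping
(reverse-direction spliced sequences are reverse-complemented into a
common orientation). Pooling gives the pair one consistent length
decision; grouping each direction separately can choose different
length groups for the same pair — near-identical copies readily induce
that asymmetry — and discarding such pairs as inconsistent would delete
exactly the edges whose conflict the resolution stage needs to see.

Spans within 10 kb form one group. Otherwise spans are histogrammed in
1-kb windows anchored at the minimum span; between each pair of
neighbouring histogram peaks, the lowest valley window splits the set
iff its count is below 90% of the right peak's count (leftmost lowest
window on ties; the valley window joins the left group). Within a
group, paths in windows holding fewer than half the modal count are
discarded; the remaining distinct spliced sequences are aligned all
against all (edlib, global), a valid match requiring each sequence to be
covered to ≥ 95% of the longer one's length at identity ≥ `si_min`. The
identity floor guards against spurious low-identity matches that pure
coverage would admit. The consensus is a modal-window path matching the
most others (ties: higher path score, shorter span, lexicographic read
chain); its match count, self included, is the high-scoring path number
NP. Identical read chains are counted by multiplicity without
re-alignment, and at most `consensus_max_seqs` (default 40) distinct
sequences enter the quadratic alignment step — chains beyond the cap
simply do not add to NP, a deliberate bias toward undercounting support
rather than overpaying for it.

Group selection: with a known gap length, the group whose consensus
span is nearest wins. Otherwise the comparison starts at the group with
the highest window frequency and walks toward longer groups, advancing
while the longer group's NP exceeds half the current one's (exactly two
groups always yield the longer — a tandem array's one-unit group is a
shortcut artifact, not a candidate). A single unsplittable group
spreading more than 100 kb marks a complex repeat and the pair
contributes no connection.

## Connection graph and conflict resolution

Edges carry NP and the consensus fill. For each anchor end, CI is the
second-largest incident NP over the largest (0 with fewer than two
edges); an end with CI > `ci_max` (default 0.75) has conflicting
connections. Resolution is iterative and greedy: in each round the
mutual-best pairs (each end's largest-NP edge pointing at the other)
are found; pairs with both ends non-conflicting commit first, highest
NP first, one per round; when none exists, the highest-NP mutual-best
pair with at least one non-conflicting end commits — the conflicted
partner is being claimed by its most confident connection, and deleting
its other edges can release further ends in later rounds. A stated
both-ends-clean rule alone cannot resolve the canonical two-conflict
chain (the 215/211 vs 218/211 situation), which is resolved exactly by
this one-sided relaxation; the relaxation never fires while any fully
clean pair remains. Edges joining the two ends of the same anchor are
kept for CI computation but never committed. Optional grouping/order
constraints veto edges between different groups or non-consecutive
order indices before resolution starts.

Committed links form a matching on ends; chains of anchors and fills
become super-contigs, contigs entered tail-first are
reverse-complemented, and cycles are broken at their minimum-NP edge
(the least-supported link is the least trustworthy). Gap filling with a
known length reruns the targeted search between the two flanking ends
and accepts the nearest group unless its span deviates from the stated
gap length by more than 50%.

## Synthetic data: what it emulates and what it does not

The generator tiles a genome from i.i.d. uniform unique sequence,
segmental-duplication pairs mutated to a requested identity (edits at
rate 1 − identity: 80% substitutions, 10% single-base insertions, 10%
deletions) and tandem arrays with per-unit divergence. Reads start
uniformly, lengths are lognormal (σ = 0.3, floor 1 kb) around the
requested mean, errors are substitutions:insertions:deletions at 2:1:1,
and total bases track the requested depth within a few percent. Contigs
are the unique stretches extended 5 kb into each flanking repeat
(configurable), which plants junction-read territory at every gap; the
repeats themselves are withheld, and true adjacency is recorded for
auditing. The bundled overlap detector seeds candidate pairs with
shared window-minimum k-mer hashes (k = 15, window 19; hashes kept
below 2^52 so the float-based window-minimum filter compares exactly),
clusters them by diagonal so tandem units yield one candidate per
offset, subsamples the hash space on large inputs, and verifies every
candidate with a banded global edlib alignment, so reported match
counts are exact.

Not emulated: chimeric reads, adapter artifacts, non-uniform coverage,
heterozygosity, and the recall profile of a production aligner. Passing
tests therefore demonstrate the algorithm's behaviour under clean
repeat structure and random errors — they do not certify performance on
real data, where aligner recall and library artifacts add failure modes
upstream of this tool.

## Problem sizes in the test suite

The acceptance properties run on ~345-kb genomes (unique flanks of
60–70 kb around a 30-kb duplication pair and a 25-kb withheld unique
spacer) at 30× depth, 9-kb mean reads, 1% error, across 20 seeds for
the chimera audit; the conflict-veto fixture uses 99.8% copy identity,
and the tandem fixture a 3 × 20 kb array at 99.9% unit identity with
0.5% read error. These sizes keep each seeded end-to-end run at a few
tens of seconds while preserving every regime the properties probe:
repeats longer than any read, copies on either side of the ~99% read
accuracy boundary, and unit-length path quantisation. Unit tests use an
error-free 112-kb fixture whose assembly must reproduce the genome byte
for byte.

## Known limitations

Automated resolution is weaker than resolution with optical maps or
genetic maps: the one-sided relaxation generalises the confident-first
narrative but cannot use external evidence, and genuinely symmetric
conflicts stay unjoined by design. NP saturates at the consensus
alignment cap, so CI between two very well supported edges compares
capped counts. Complex repeats are detected and skipped, never
assembled. Consensus fills are a representative path's spliced
sequence; base-level polishing is downstream work. Only PAF is ingested;
SAM/BAM users convert upstream.
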