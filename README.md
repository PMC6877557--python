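# repeatspan

Long-read assemblies of complex genomes fragment at segmental duplications
and tandem repeats: string-graph and OLC assemblers compress near-identical
repeat copies, so the unique sequence comes out as well-assembled contigs
surrounded by unresolved gaps. `repeatspan` takes those pre-assembled
contigs, the error-corrected long reads, and their all-vs-all alignments
(PAF), and reconnects the contigs across the repeats — assembling each
repeat copy separately and attaching it to its true flanking sequence,
while refusing joins whose support is ambiguous. It is aimed at people
finishing genome assemblies: closing gaps between contigs, filling
known-length scaffold gaps, and auditing contig order.

## The method

Contigs at or above 50 kb become **anchoring nodes**; shorter contigs are
pooled with the reads. Every node in the overlap graph has two explicit
ends (head/tail), edges attach to ends, and a traversal entering a node
through one end must leave through the other — so a walk is a valid
tiling path. An alignment between sequences S1 and S2 is summarised by
its aligned span lengths OL1, OL2, identity SI, overhang lengths OH1, OH2
(unaligned sequence between the aligned span and the engaged end —
evidence of divergence) and extension lengths EL1, EL2 (sequence
protruding past the partner). Two scores drive the search:

    OS  = (OL1 + OL2) · SI / 2
    ES2 = OS + EL2/2 − (OH1 + OH2)/2      (S2 extending S1)

From each anchor end, tiling paths to other anchors are generated three
ways: greedy extension by best OS, greedy extension by best ES (both with
backtracking out of dead ends), and repeated random walks that sample
each step proportionally to ES. A path ends on the first read linked to
another anchor. The pooled, de-duplicated paths between an anchor-end
pair are histogrammed by spliced length in 1-kb windows; qualifying
valleys split them into groups (a tandem array yields groups at unit
multiples), each group elects a consensus path by mutual alignment, and
one group is selected — nearest the gap length when it is known.

The **connection graph** keeps only anchor ends; an edge carries NP, the
number of paths matching the consensus. For each end with largest and
second-largest incident weights NP_im ≥ NP_in, the **conflict index** is
CI = NP_in / NP_im. Two near-identical repeat copies produce CI close to
1; ends with CI above 0.75 are never joined unless committing a
competitor's confident connection elsewhere releases them. Committed
links are concatenated with their consensus fills into super-contigs
(FASTA + AGP v2.1).

## Worked example

The built-in simulator plants a 30-kb segmental-duplication pair at 97%
identity (plus one withheld unique spacer region) in a 345-kb genome,
fragments it into four contigs the way an assembler would, and simulates
30× corrected reads at 1% error together with their all-vs-all PAF:

```python
from repeatspan import Params, connect_contigs
from repeatspan.synthetic_data import make_segdup_fixture

fx = make_segdup_fixture(seed=1)
res = connect_contigs(fx.contigs, fx.reads, fx.paf, Params(seed=1))
print(f"estimated read accuracy alpha = {res.alpha:.4f}")
for e in res.resolution.committed:
    print(f"join {e.end_a.node_id}:{e.end_a.end} -- "
          f"{e.end_b.node_id}:{e.end_b.end}  NP={e.np}  "
          f"fill={len(e.consensus_seq)} bp")
for s in res.super_contigs:
    print(f"{s.id}: {s.length} bp")
```

prints

```
estimated read accuracy alpha = 0.9793
join ctg01:tail -- ctg02:head  NP=40  fill=19995 bp
join ctg02:tail -- ctg03:head  NP=40  fill=15000 bp
join ctg03:tail -- ctg04:head  NP=40  fill=19984 bp
super_0001: 344979 bp
```

All three gaps close (the two repeat gaps and the unique spacer), every
join connects truly adjacent contigs, and the single super-contig
recovers the 344,987-bp genome to within a few bases of indel wobble
from the 1% read error. `alpha` is the base accuracy estimated from
overlap identities; with error-free reads it is exactly 1.0 and the
reconstruction is byte-identical. Re-running the same fixture at 99.8%
copy identity instead leaves the four repeat-flanking contig ends with
conflict indices near 1 and commits no join across the duplication —
ambiguity is reported, not guessed.

The same pipeline is available from the shell:

```
repeatspan simulate --kind segdup --seed 1 --out fixture/
repeatspan assemble --contigs fixture/contigs.fa --reads fixture/reads.fa \
    --paf fixture/overlaps.paf --out out/ --seed 1
repeatspan fill-gaps --scaffold-gaps gaps.tsv --contigs ... --reads ... --paf ...
```

`out/` contains `super_contigs.fa`, `assembly.agp`, the fill sequences
and a per-edge join report (NP, both conflict indices, status).

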