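# Methods

## The graph model

For a read set R over {A,C,G,T} and an odd k, the bi-directed de Bruijn
graph models both strands of the DNA at once.  A vertex is a *k-molecule*:
the pair (ŝ, rc(ŝ)) of a canonical k-mer — the lexicographically smaller of
a k-mer and its reverse complement — and its reverse complement.  Odd k
guarantees no k-mer is its own reverse complement, so the canonical choice
is strict.  Every (k+1)-mer z occurring in R* = R ∪ rc(R) induces one
bi-directed edge between the molecules of its two k-mers x = z[1..k] and
y = z[2..k+1]; the edge carries an arrowhead at each endpoint (▷ = the
molecule's canonical strand takes part in the k−1 overlap, ◁ = its reverse
complement does).  A walk is valid when the incoming arrowhead at every
intermediate vertex equals the outgoing one — the condition under which
consecutive edges read the same physical strand.

Sequences are packed 2 bits per base (A=0 < C=1 < G=2 < T=3, leftmost base
most significant) so integer comparison *is* lexicographic comparison and
canonicalisation never decodes.

## Construction by sorting

Construction is a sort-reduce pipeline rather than a hash table, which is
what makes the out-of-core mode possible:

1. **Edge records.**  Every clean (k+1)-window of R* (windows containing
   ambiguous bases are skipped, the count logged) is canonicalised by a
   case analysis — flip each endpoint to its canonical k-mer, recording
   head orientations, then flip-swap the record if the endpoints are out
   of order — and packed big-endian into ⌈(4k+2)/8⌉ bytes as
   (û, v̂, h1, h2).  A self-loop record (u,u,◁,◁) is rewritten to (u,u,▷,▷):
   the two denote the same edge under the flip-swap equivalence (z = AAAA
   versus z = TTTT), and without the rule duplicate removal would fail to
   merge them.  Parallel edges differing in heads are genuinely different
   overlaps and are *not* merged.
2. **Sort.**  In memory: LSD radix sort with 8-bit digits over the byte
   matrix (the per-digit stable permutation is numpy's stable integer
   argsort, itself a counting/radix sort).  Out of core: runs of at most M
   payload bytes are radix-sorted and spilled, then merged R-ways with
   R = max(2, ⌊M/B⌋−1) through B-byte block cursors and a tournament heap
   (ties broken by run index, so output is byte-reproducible).  Pass count
   is 1 + ⌈log_R(runs)⌉; an instrumented telemetry object tracks runs,
   passes and peak resident payload so tests can assert the budget without
   OS probing.
3. **Reduce.**  Equal adjacent records collapse into one edge with a
   multiplicity.  Because R* contains both strands, every multiplicity is
   exactly twice the forward-only count.
4. **Vertices and adjacency.**  Endpoint codes are deduplicated and sorted;
   dense ids are ranks; each edge is indexed under both endpoints
   (self-loops once).

Both modes produce identical graphs; `auto` switches to external sorting
when estimated record bytes exceed half the memory budget.

## Compaction via the doubled graph

Pointer jumping applied directly to bi-directed chains can loop, because a
bi-directed edge is traversable in both directions.  Compaction therefore
first doubles the graph: each molecule v becomes signed nodes v⁺ (reading
the canonical strand) and v⁻, and each edge (u,v,h1,h2) becomes the arc
u^s(h1) → v^s(h2) plus its complement v^s(h2)′ → u^s(h1)′, with s(▷)=+,
s(◁)=−.  Bi-directed reachability in the original graph equals directed
reachability in the doubled graph; the package regression-tests this
against an exhaustive walk-rule search on random graphs, which pins down
the arc orientation convention.

Branching signed nodes (in- or out-degree above one) and their incident
arcs are set aside; the remainder is a disjoint union of directed paths
and cycles.  Paths are ranked either by in-memory pointer jumping
(⌈log₂C⌉+1 rounds for the longest chain C) or out of core by sort-merge
pointer doubling: the active tuple set S of (node, successor-pointer,
distance) records is sorted by target and by source through the external
sorting engine, scan-joined, and every joinable pair (x,y),(y,y′) is
replaced by (x,y′).  The per-phase join count J(S) = #{(x,y) : ∃(y,z)∈S}
strictly decreases to zero on acyclic inputs (|S′| = J(S)); if it repeats
across two consecutive phases the surviving tuples lie on cycles, which
are reported.  Note the per-phase count drops by the number of tuples
whose pointer reaches a chain end, so the decrease is strict every phase
and the phase count is logarithmic in C, but a literal per-phase halving
of |S| does not hold for a single long chain under this (doubling)
formulation — the halving bound describes a consuming pair-merge variant
that cannot reproduce the join-count behaviour implemented here.  In the
out-of-core path the per-phase sorts — the I/O-dominant cost — run through
the external engine; the set of chain tails, the resolved (tail, distance)
table and final chain assembly are in-memory maps bounded by the node
count, a deliberate desk-scale simplification.

Every maximal chain has a complementary mirror (the reversed complement
node sequence).  Each pair becomes one new molecule: its label is spelled
with k−1 overlap (the oriented label of the first node, then the
non-overlapping tail of each successor — literal concatenation would
double the overlaps), its canonical label is the smaller of the two
spelled strands, and its *name* is min{endpoint molecule names}.  The
chain whose spelling equals the canonical label maps to the new node's
"+" side.  (An alternative convention keeps the chain-sign of the min
endpoint; the resulting edge set is identical — only which strand is
called "+" differs — but it can label the lexicographically larger strand
"+", which would break canonical-label invariants in the writers and in
recompaction, so it is not used.)  Boundary arcs are re-targeted from the
chain endpoints to the new signed nodes and folded back into bi-directed
edges, keeping the multiplicity of the original boundary edge; merged
interior multiplicities are not aggregated into a single number, since no
principled combination exists.

Cycles are broken at the globally minimum signed node *of the cycle pair*
(breaking each cycle at its own minimum would rotate the mirror out of
alignment) and compacted as open chains; the dropped arc appears in the
cycle report.  A cycle of a circular sequence therefore compacts to one
node whose label has length L + k − 1, the final k−1 bases repeating the
first k−1 (the wrap).

Degenerate cases: a self-mirror chain (head and tail are the two signs of
one molecule, arising from ▷◁/◁▷ self-loops) spells an rc-palindromic
label; it is compacted alone with the head mapped to "+" and the tail to
"−", which preserves arc symmetry, but a walk threading straight through
it changes apparent strand — an intrinsic degeneracy of rc-palindromic
unitigs, logged when it occurs.

## Synthetic data

The simulator exists so every stage is testable without external data.
It generates uniform random genomes (optionally screened so all (k−1)-mers
are unique, i.e. the genome's graph is a single chain), uniformly placed
reads at a requested coverage with substitution errors at a fixed per-base
rate, optional reverse-complementing of a per-read fraction, circular or
linear placement, and deterministic tiling reads.  One global seed feeds a
named PRNG stream per purpose (positions, strands, errors), so enabling
errors does not move read positions.  Default study conditions used by the
tests and the acceptance script: a 10 kbp unique-(k−1)-mer genome with
length-100 reads tiled at step 70 for full-reconstruction compaction;
20,000 reads of length 70 at k=21 from a 100 kbp genome for the
out-of-core/in-memory equivalence (≈2.0M edge records, sorted under a
1 MiB budget with 64 KiB blocks, forcing ≥2 merge passes); a 2 kbp
circular genome for cycle detection.  The model is substitution-only and
single-end — indels, quality strings and platform error profiles add
nothing to the graph algorithms under test — so passing tests demonstrate
algorithmic correctness on idealised reads, not robustness to real
sequencing artefacts.

## Numerical and interface choices

- k must be odd and is validated everywhere; even k raises with an
  explanation.  k ≤ 31 keeps endpoint codes in one machine word, but the
  implementation accepts larger k (Python integers).
- Records are fixed-width big-endian so byte order equals integer order;
  all sorts are stable, making every output byte-reproducible.
- The edge sort key (û, v̂, h1, h2) fixes a total order that the vertex
  collection step reuses.
- TSV dialect: `#k=` header, one tab-separated row per edge with heads
  `>`/`<`, rows in label-canonical order (independent of internal vertex
  numbering, so write→read→write is byte-stable); isolated vertices are
  declared on `V` lines so a fully compacted single-unitig graph survives
  the round trip.  GFA1 maps ▷→`+`, ◁→`−` with `(k−1)M` overlaps; the
  VELVET-internal graph dialect is deliberately not emitted.
- CLI defaults: k=21, 512 MiB memory budget, 256 KiB blocks, mode auto.
  Exit codes: 0 success, 1 validation, 2 I/O.

## Known limitations

- No error correction, tip clipping or bubble popping: multiplicity
  filtering (`min_multiplicity`) is the only noise control.
- The walk-spelling checker enumerates k-mer occurrences across labels and
  is intended for verification at test scale, not alignment.
- The out-of-core list ranking keeps per-node resolution state in memory
  (see above); only the sorting is external.
- rc-palindromic unitig labels confound strand bookkeeping (flagged, not
  resolved — the usual situation in bi-directed assemblers).
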