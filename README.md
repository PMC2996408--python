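# bidbg — bi-directed de Bruijn graphs by sorting

`bidbg` builds the bi-directed de Bruijn graph of a short-read set and
compacts its non-branching chains into unitigs.  It is written for people
working on assembly infrastructure: the graph is constructed by *sorting*
canonical edge records rather than by hashing k-mers, so the same pipeline
runs fully in memory or out of core under an explicit memory budget, and
chain compaction runs either by in-memory pointer jumping or by external
sort-merge list ranking with join-count cycle detection.

## The model

DNA is double-stranded, so a k-mer and its reverse complement are the same
physical sequence.  For odd k, each such pair is represented by one
**k-molecule** vertex (ŝ, rc(ŝ)), where ŝ — the *canonical* k-mer — is the
lexicographically smaller of the two.  Every (k+1)-mer z of the reads and
their reverse complements induces one **bi-directed edge** between the
molecules of x = z[1..k] and y = z[2..k+1], carrying an arrowhead at each
endpoint (▷: the canonical strand takes part in the k−1 overlap; ◁: the
reverse complement does).  A walk is valid when, at every intermediate
vertex, the incoming arrowhead equals the outgoing one — this is what keeps
a walk on one physical strand, and it is the sense in which the graph
"spells" the underlying sequence.

Construction is: canonicalise one fixed-width integer record per
(k+1)-window → sort (LSD radix in memory, or R-way external merge under a
budget of M bytes with B-byte blocks, R = ⌊M/B⌋−1) → collapse duplicates
into multiplicities → collect vertices and adjacency.  Compaction doubles
the graph into signed nodes v⁺/v⁻ (one directed arc pair per bi-directed
edge — directed reachability in the doubled graph equals bi-directed
reachability in the original), prunes branching nodes, ranks the remaining
paths, and merges each maximal chain with its reverse-complement mirror
into a single relabelled node.  See `docs/methods.md` for the details and
the design choices.

## Worked example

The six reads ATGG, CCAT, GGAC, GGTC, TGGA, TGGT (4-mers observed from the
fragment ATGGACCAT and its reverse complement ATGGTCCAT) at k=3:

```python
import bidbg as b

g = b.build_graph(b.ReadSet.from_sequences(
    ["ATGG", "CCAT", "GGAC", "GGTC", "TGGA", "TGGT"]), 3)
for row in g.edge_keys():
    print(*row)
print("walk spelling TGGACCAT:", b.read_is_spelled(g, "TGGACCAT"))
```

prints

```
ACC CCA > > 2
ACC GAC < < 2
ATG CCA > < 4
CCA GGA < > 2
GAC GGA < < 2
walk spelling TGGACCAT: True
```

Five molecules, five bi-directed edges.  Each multiplicity counts
(k+1)-mer occurrences over reads *plus* reverse complements, so every
count is even (ATG–CCA gets 4: ATGG and CCAT are each other's reverse
complements).  The final line confirms the graph admits a valid
bi-directed walk spelling the source fragment with its first letter
omitted — the reconstruction the graph exists to support.  Note there is
no edge between molecules that merely overlap by k−1 without being
adjacent in a read: building from the single read AATGCATC leaves AAT and
ATC unconnected.

## Command line

```
$ bidbg simulate --genome-length 5000 --coverage 12 --read-length 70 \
      --rc-fraction 0.5 --seed 7 --out-prefix sim
$ bidbg build --reads sim.reads.fa -k 21 --mode auto --out-prefix graph --format both
$ bidbg compact --graph graph.edges.tsv --out-prefix unitigs
$ bidbg stats --graph unitigs.edges.tsv
k=21 vertices=1 edges=0 total_mult=0 self_loops=0 compacted=1
```

The 858 simulated reads produce 83,574 edge records collapsing to 4,956
unique edges over 4,957 molecules (`graph.run.json` records these counts,
along with sort runs and merge passes in external mode); compaction
collapses the whole graph to a single unitig spelling the 5 kbp genome or
its reverse complement.  `--mode external --memory-mb 1` runs the same
build under a 1 MiB sorting budget with byte-identical output.  Graphs are
written as a TSV edge list and/or GFA1.

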