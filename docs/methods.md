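# Methods

## The problem and the model

A short-read assembler's output graph stores one nucleotide string per
edge; adjacent edges share a fixed overlap of `k−1` bases (55 for the
default SPAdes word size), and every edge has two faces related by reverse
complement, with link symmetry `a+→b+ ⇔ b−→a−`. A genome — and therefore
a gene — is spelled by a path: the first edge from its start offset, each
following edge minus its leading overlap, the last edge truncated at an
end offset. `orfgraph` treats gene finding as path finding: given partial
alignments of known family members (anchor-paths), reconstruct every
plausible complete coding path through the graph, then filter, classify,
cluster and summarise the candidates.

Coordinates are 0-based half-open throughout. A base inside an overlap
has one `(edge, orientation, offset)` name per adjacent edge; the library
treats these representations as a single physical base
(`equivalent_positions`), which matters everywhere a search starts or
ends on an edge boundary: codon-site deduplication, path-enumeration
endpoints, and reachability all operate on equivalence classes. Graph
traversal is canonical — a walk stays on its current edge until the last
base and then branches into successors at offset `overlap` — so no base
is read twice.

## Anchors

The built-in aligner enumerates maximal simple oriented-edge paths from
source edges (bounded by a path budget; exceeding it raises an error
directing the user to externally computed alignments), six-frame
translates each spelling, and locally aligns every query protein
(BLOSUM62, gap open −11 / extend −1). A hit is kept when it covers at
least `min_protein_fraction` (default 0.8) of the query at
`min_identity` (default 80 % over the aligned span); query-residue
coverage, not alignment columns, is counted. Ingested external
alignments additionally honour an e-value cut (default 1e−9) and a 0.9
length fraction for profile-model hits. Anchors spelling fewer than
60 nt are dropped — shorter than any profile model at 90 % coverage of a
25-state model, the smallest in common use for this family.

An anchor contained in another anchor's path *in the same reading frame*
is redundant and removed; frame agreement means the inner anchor's
start phase equals the outer anchor's phase at the shared offset.
Cross-strand containment is never treated as same-frame. Identical
anchors keep one copy.

## Codon search

From the anchor's right boundary a BFS explores forward, carrying the
partially consumed codon (`frameshift string`). A state completing a
stop codon (TAA/TAG/TGA) is terminal: no reading frame continues through
an in-frame stop, so exploration of that branch ends. All distinct stop
sites within `max_dist` are reported with their minimum distance.

The start side runs the same machinery on the reverse-complement view:
walking upstream on the forward strand is walking forward on the
opposite strand, where a forward start codon appears as its reverse
complement. Distance 0 denotes the anchor's own first codon, which is
read off the anchor path itself rather than re-traced through the graph
— re-tracing could wander onto sibling edges that share the boundary
overlap but do not contain the anchor. Upstream exploration is *not*
pruned at in-frame stops; a start beyond one is flagged `after-stop`
(any such start would produce a candidate with an internal stop, which
the builder later rejects — the flag records the observation rather than
acting on it). A Shine–Dalgarno-like signal (≥ 4/6 matches to AGGAGG,
5–15 nt upstream on the same path) sets `has-sd`; the motif and window
are deliberately permissive and the flag is informational only, never a
filter.

Distances are multiples of 3 by construction. Visited states are keyed
by (position, consumed-in-codon, buffer), bounding the state space by
roughly 12 × the number of base positions, which guarantees termination
on cyclic graphs. Two distinct codons can share their first base when
the second or third base lies past a branch point, so discovered sites
are keyed by both codon endpoints. `max_dist` defaults to
`max_restorable_length − anchor length`, floored at 0; no separate
codon-search bound is introduced. Anchors produced by the built-in
aligner are codon-aligned (`frame_tag = 0`); for boundary phases ≠ 0
(possible only for external anchors with the permitted ±2 nt slop) the
codon spanning the boundary is skipped and scanning starts at the first
fully in-frame codon.

## CDS generation

`reachable_edges` computes, exactly, the oriented edges lying on at
least one bounded-length path between two positions, via a forward and a
backward Dijkstra over edges (since repeated edges are allowed, the
concatenation of a shortest way in and a shortest way out is always
realisable, making the min-sum criterion exact). `enumerate_paths` then
runs a breadth-then-lexicographic search restricted to that whitelist,
emitting at most `max_paths_per_pair` (default 1000) paths of spelled
length ≤ `max_restorable_length` (default 3000 nt, inclusive — "below
3000" is read as ≤ 3000 and the boundary is pinned by tests) and setting
a truncation flag when the cap fires. Edges may repeat within a path;
the length bound, not simplicity, terminates the search, so
tandem-repeat genes remain representable.

Each prefix × suffix combination is concatenated with the anchor
(path joins are validated by re-spelling), and a concatenate survives
only if its length is within bounds and a codon multiple, it starts with
a configured start codon (default bacterial ATG/GTG/TTG), ends with a
stop, contains no internal in-frame stop and no N. The internal-stop
check is performed on the final sequence even though stop-side search
already prunes — prefix/suffix paths other than the one on which a codon
was discovered may introduce stops. Translation uses the bacterial code
(NCBI table 11) without forcing an initial methionine. Duplicates are
merged on the amino-acid sequence, per call and again globally across
anchors.

## Ranking, contig filtering, classification

The reliability triplet is *(start-distance likelihood, read coverage,
path length)*, compared lexicographically. The likelihood is the
fraction of training distances (gene start → model-hit start, from a
user-supplied table) within ± `binSize` (default 150 nt) of the
candidate's distance; models absent from training, and plain protein
anchors, carry no evidence and score 1.0. Coverage is the
length-weighted mean of per-edge coverage tags from the GFA (DP as-is,
KC divided by `length − overlap`); graphs without tags score 0.
Re-aligning reads is out of scope.

An edge is *unique* if its length exceeds `minLength` (default 300 nt;
the value interacts with assembly N50 and is exposed in configuration)
and both of its end nodes branch. Node identity is implicit in the
edge-centric model; degrees are recovered from co-linked edges
(out-siblings/in-siblings). The degree condition is implemented exactly
as specified (outdegree of the start node > 1 and indegree of the end
node > 1); a configuration switch provides the inverted `== 1`
convention since the printed form inverts common usage. Two paths are
*compatible* when one is contained in the other (step level) or a suffix
of one equals a prefix of the other, on either strand. A candidate
sharing a unique edge with a contig it is not compatible with is
removed, and the offending contig is recorded. A candidate whose path is
a sub-path of a contig can never be removed (soundness).

Similarity classification scores each candidate against the query
database. The identity metric counts identically matched residues over
the shorter sequence's length in an end-gap-free global alignment; for
the substitution-only comparisons that dominate this use it equals
aligned-region identity, but unlike aligned-region identity it cannot be
inflated by a degenerate few-column alignment. Verdicts: below the
reliable threshold (80 %) → `candidate`; at or above → `reliable`,
refined to `reliable-novel` (> 90 %, < 100 %) and `reliable-known`
(exact). The pipeline additionally discards candidates below
`retain_identity` (default 80 %) before clustering — this realises the
removal of thioredoxin-family cross-hits, which share domains with the
toxins but not 80 % identity. With both thresholds at their default the
`candidate` verdict only survives when `retain_identity` is lowered.

## Clustering and representatives

Two candidate proteins are related when one is a substring of the other
or their identity exceeds PI (default 90 %); clusters are connected
components (single linkage) of that relation, computed over canonically
ordered members so the partition is input-order invariant. *Long cluster
edges* are graph edges > 1 kb (default) appearing in any member's path.
Members are scanned from lexicographically largest triplet to smallest
(ties broken by candidate id); a member is kept as representative iff it
contains a long cluster edge not yet covered, so the representative set
covers every long cluster edge by construction. The scan direction
deserves a note: a literal least-reliable-first scan contradicts the
goal of reporting the most reliable candidates, so descending order is
the default and `scan_order="ascending"` restores the literal
behaviour. A cluster without long edges keeps its single most reliable
member.

## Synthetic fixtures

The generator embeds complete CDSs (default 300 codons, flanks of
300 nt) in random DNA, tiles the genome into edges overlapping by k
(default 55), and optionally adds structure: *bubbles* duplicate
internal gene edges with ~2 % substitutions (stop-safe, so every branch
stays coding), alternating with unmodified spacer edges so n bubbles
yield exactly 2ⁿ alternative coding paths; a *tangle* gives two gene
variants one shared central repeat edge, so no contig spells either gene
completely. The left flank always ends with an in-frame stop codon —
closing the upstream reading frame immediately before the start codon,
as a real gene's upstream context eventually does — which makes the
annotated start the unique recoverable start and the ground truth
well-defined. Contigs are unitigs (maximal non-branching paths), the
same mechanism that fragments multi-copy genes in real assemblies;
coverage tags are 30× on genome edges, 15× on bubble branches and 60× on
the shared repeat. Everything is a pure function of the seed, and the
same seed yields byte-identical GFA output.

What the fixtures do *not* emulate: sequencing error, chimeric links,
uneven or strain-mixture coverage, and assembler-specific graph
simplification. Passing tests therefore demonstrate correctness of the
path/codon/filter machinery under clean topology, not robustness to
noisy real assemblies; on real data the contig filter and the coverage
component of the triplet carry correspondingly more weight.

## Problem sizes and numerical choices

The test suite and the acceptance script run at desk scale by design:
random oracle graphs have ≤ 10 edges and ≤ 10⁴ paths, fixtures carry
single genes of ≤ 1000 codons with ≤ 10 bubbles, and the brute-force
aligner is bounded by an explicit path budget (default 20 000 maximal
paths). These sizes make exhaustive, independently implemented oracles
(full path enumeration, subset search) feasible as ground truth; the
algorithms themselves are written against the general bidirected model
and carry no small-graph assumptions. Ties everywhere are broken by
deterministic lexicographic keys, so identical inputs produce
byte-identical outputs.

## Known limitations

* The built-in aligner is exponential in graph tangledness and is meant
  for small graphs and fixtures; production-scale anchor discovery should
  come from a dedicated sequence/profile-to-graph aligner via the
  anchors TSV.
* Profile-model anchors are ingested, never computed: there is no
  profile-HMM Viterbi over the graph, and e-values are taken from the
  ingesting tool.
* The unique-edge heuristic is deliberately simple and, as configured by
  default, misclassifies long unbranched edges as non-unique; both
  degree conventions are exposed.
* Candidates containing N anywhere are discarded rather than translated
  permissively.
* The frameshift string tracks reading frame across edges; actual
  frameshifting genes (programmed or erroneous) are out of scope — each
  candidate is a single uninterrupted frame.
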