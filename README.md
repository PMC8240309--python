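# orfgraph

Recovery of **complete protein-coding genes from (meta)genomic assembly
graphs**, for gene families whose members are fragmented across contigs.

Large multi-copy gene families — the motivating case is the Cry/Cyt/Vip
insecticidal proteins encoded on *Bacillus thuringiensis* plasmids — are
routinely shattered by short-read assembly: near-identical gene copies
collapse into bubbles and shared repeat edges, so each contig carries only a
gene fragment. Contig-based gene finders then report partial genes. The
complete gene, however, is still *spelled by a path* of the assembly graph.
`orfgraph` searches for those paths:

1. **Anchors.** Known proteins of the family are aligned to the graph
   (a built-in brute-force six-frame aligner for desk-scale graphs, or an
   ingested TSV of alignments from a dedicated graph aligner). Alignments
   covering ≥ 80 % of a protein become *anchor-paths*; anchors contained in a
   longer anchor in the same reading frame are dropped.
2. **Codon search.** From each anchor boundary a breadth-first search with a
   *frameshift string* (the 1–3 nt of the partially consumed codon, carried
   across edge boundaries) finds every reachable in-frame start codon
   (upstream; ATG/GTG/TTG, never pruned at upstream stops but flagged
   `after-stop`, with Shine–Dalgarno-like motifs flagged `has-sd`) and stop
   codon (downstream; exploration ends at each stop).
3. **CDS generation.** For every (start, stop) pair, all connecting
   prefix/suffix paths are enumerated (DFS-restricted to edges reachable
   within the length budget, at most 1000 paths per pair, total length
   ≤ 3000 nt) and concatenated with the anchor; concatenates with internal
   in-frame stops are discarded and duplicates are merged on the translated
   protein.
4. **Filtering and ranking.** Candidates that share a *unique edge*
   (length > 300 nt between branching nodes) with an assembler contig path
   without being contained in it or dovetailing with it contradict the
   contig and are removed. Survivors are classified against the query
   database (≥ 80 % identity = reliable; > 90 % and < 100 % = reliable-novel;
   100 % = reliable-known) and ranked by the lexicographic triplet
   *(start-distance likelihood, read coverage, path length)*.
5. **Clustering.** Single-linkage clustering (substring relation or > 90 %
   identity) groups near-identical candidates; within each cluster a greedy
   scan keeps the most reliable members until every *long cluster edge*
   (> 1 kb) is covered by a representative.

A synthetic-fixture generator builds assembly graphs with known embedded
genes (serial bubbles, shared-repeat tangles, unitig contigs), so the whole
pipeline is testable without any external data.

## Worked example

Generate a fixture whose single gene crosses two bubbles, then run the
pipeline with the true protein as the query database:

```bash
orfgraph fixture --seed 4 --n-bubbles 2 --out fx
# -> wrote fixture with 1 gene(s), 7 contig(s) to fx

orfgraph run --gfa fx/graph.gfa --proteins known.faa \
    --contig-paths fx/contigs.paths --out run --report-known
```

The run prints per-stage counts:

```
anchors: 4
anchors_after_subpath_filter: 4
candidate_orfs: 4
after_contig_filter: 4
after_similarity_filter: 4
clusters: 1
representatives: 1
main_representatives: 1
```

Four anchors are found (one per bubble-branch combination), each extends to
exactly one candidate coding sequence, and the four near-identical proteins
collapse into one cluster whose representative is the true gene.
`run/representatives.faa` then contains:

```
>orf0001 anchor=known verdict=reliable-known
MVLSLLLLTLAHPAYDRGSIDPWNLCRRYFFCPVLDCARLAHGRLIGTRELLLSLPFCPII...
```

`verdict=reliable-known` records that the recovered protein matches a
database entry at 100 % amino-acid identity. `run/cds_report.tsv` lists each
candidate's graph path and ranking triplet — the representative spells
`E02+,E03+,E04+,E05+,E06+,E07+` (903 nt, coverage 30×), while the bubble
variants score lower coverage (their branch edges carry 15×):

```
orf_id   anchor_query  path                            nt_len  likelihood  coverage
orf0001  known         E02+,E03+,E04+,E05+,E06+,E07+   903     1.0000      30.00
orf0002  known         E02+,E03+,E04+,E05+,E06b+,E07+  903     1.0000      27.99
```

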