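"""Synthetic assembly-graph fixtures with known embedded genes.

The generator embeds complete coding sequences in random flanking DNA,
cuts the resulting genome into overlapping edges (emulating a de Bruijn
assembly graph at word size k), and optionally complicates the topology:

* *bubbles* -- an internal edge of the gene region is duplicated with a
  few substitutions, emulating near-identical gene variants collapsing
  into parallel branches;
* a *tangle* -- two gene variants share one central repeat edge, so
  neither gene is spelled by any single contig.

Contigs are derived as unitigs (maximal non-branching paths), which is
what fragments multi-copy genes in real assemblies.  Everything is a
deterministic function of the seed; the same seed yields byte-identical
GFA output.  What this emulates -- and what it does not (sequencing
error, uneven coverage, strain mixtures) -- is discussed in the package
methods notes.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np

from ._align import translate
from .graph import (
    AssemblyGraph,
    GraphPath,
    flip,
    spell,
    write_gfa,
)

__all__ = [
    "FixtureSpec",
    "FixtureTruth",
    "GeneTruth",
    "generate_fixture",
    "generate_contig_filter_graph",
    "random_cds",
    "unitig_contigs",
]

STOPS = {"TAA", "TAG", "TGA"}
_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in STOPS and a + b + c != "ATG"
]


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))


def random_cds(rng: np.random.Generator, aa_len: int) -> str:
    """ATG + aa_len-1 sense codons + TAA; no internal stops."""
    body = "".join(rng.choice(_CODONS, size=aa_len - 1))
    return "ATG" + body + "TAA"


@dataclass(frozen=True)
class FixtureSpec:
    genes: tuple[str, ...] = ()  # complete CDSs (start..stop); generated if empty
    gene_aa_len: int = 300
    n_genes: int = 1
    n_bubbles: int = 0
    bubble_divergence: float = 0.02  # substitutions per branch base
    tangle: bool = False
    k: int = 55  # overlap between adjacent edges
    flank: int = 300
    contig_policy: str = "unitigs"  # "unitigs" | "genome" | "none"
    coverage: float = 30.0
    seed: int = 0

    def __post_init__(self):
        for cds in self.genes:
            _check_cds(cds)
        if self.contig_policy not in ("unitigs", "genome", "none"):
            raise ValueError(self.contig_policy)


def _check_cds(cds: str) -> None:
    if len(cds) % 3 != 0:
        raise ValueError("CDS length must be a multiple of 3")
    if cds[:3] not in ("ATG", "GTG", "TTG") or cds[-3:] not in STOPS:
        raise ValueError("CDS must begin with a start codon and end with a stop")
    internal = [cds[i : i + 3] for i in range(3, len(cds) - 3, 3)]
    if any(c in STOPS for c in internal):
        raise ValueError("CDS contains an internal stop codon")


@dataclass
class GeneTruth:
    gene_id: str
    path: GraphPath
    nt_seq: str
    aa_seq: str
    contigs: list[str] = field(default_factory=list)


@dataclass
class FixtureTruth:
    genes: list[GeneTruth] = field(default_factory=list)


class _Builder:
    """Accumulates genomes cut into edges sharing ``k`` overlapping bases."""

    def __init__(self, k: int):
        self.k = k
        self.edges: dict[str, str] = {}
        self.links: list = []
        self.counter = 0

    def new_id(self, prefix: str = "E") -> str:
        self.counter += 1
        return f"{prefix}{self.counter:02d}"

    def tile(self, genome: str, cuts: list[int], ids: list[str] | None = None) -> list[str]:
        """Cut ``genome`` at internal positions ``cuts`` into edges that
        overlap by k; returns edge ids in path order."""
        k = self.k
        bounds = [0] + sorted(cuts) + [len(genome)]
        names = []
        for i in range(len(bounds) - 1):
            lo = bounds[i] - (k if i > 0 else 0)
            hi = bounds[i + 1]
            seq = genome[lo:hi]
            if len(seq) <= k:
                raise ValueError("segment too short for overlap")
            name = ids[i] if ids else self.new_id()
            self.edges[name] = seq
            names.append(name)
        for a, b in zip(names, names[1:]):
            self.links.append(((a, "+"), (b, "+")))
        return names

    def add_branch(self, after: str, before: str, seq: str, name: str) -> None:
        self.edges[name] = seq
        self.links.append(((after, "+"), (name, "+")))
        self.links.append(((name, "+"), (before, "+")))

    def build(self, coverage: dict[str, float] | None) -> AssemblyGraph:
        return AssemblyGraph(self.edges, self.k, links=self.links, coverage=coverage)


def _stop_safe_substitute(rng: np.random.Generator, seq: list[str], codon_start: int, p: int) -> None:
    """Substitute seq[p] in place with a base that keeps the codon at
    ``codon_start`` out of the stop set."""
    original = seq[p]
    choices = [b for b in "ACGT" if b != original]
    for idx in rng.permutation(len(choices)):
        seq[p] = choices[idx]
        codon = "".join(seq[codon_start : codon_start + 3])
        if codon not in STOPS:
            return
    seq[p] = original


def _mutate_branch(
    rng: np.random.Generator,
    genome: str,
    seg_lo: int,
    seg_hi: int,
    cds_span: tuple[int, int],
    divergence: float,
    k: int,
) -> str | None:
    """A diverged copy of genome[seg_lo - k : seg_hi] whose substitutions
    avoid the flanking overlaps and never create an in-frame stop within
    the gene; None if the branch interior is empty."""
    cds_lo, cds_hi = cds_span
    interior = [
        p
        for p in range(seg_lo + 1, seg_hi - k - 1)
        if cds_lo <= p < cds_hi - 3
    ]
    if not interior:
        return None
    n_sub = max(1, int(round(divergence * len(interior))))
    picks = rng.choice(interior, size=min(n_sub, len(interior)), replace=False)
    alt = list(genome)
    for p in sorted(picks):
        codon_start = cds_lo + 3 * ((p - cds_lo) // 3)
        _stop_safe_substitute(rng, alt, codon_start, p)
    alt_s = "".join(alt)
    aa = translate(alt_s[cds_lo : cds_hi - 3])
    assert "*" not in aa
    return alt_s[seg_lo - k : seg_hi]


def unitig_contigs(graph: AssemblyGraph) -> dict[str, GraphPath]:
    """Maximal non-branching oriented-edge paths, one strand per unitig."""
    def extendable(u, v) -> bool:
        return len(graph.successors(u)) == 1 and len(graph.predecessors(v)) == 1

    seen: set = set()
    unitigs: list[list] = []
    oriented = [(e, o) for e in sorted(graph.edges) for o in "+-"]
    for oe in oriented:
        if oe in seen:
            continue
        # walk back to the unitig's first edge
        cur = oe
        guard = 0
        while True:
            preds = graph.predecessors(cur)
            if len(preds) == 1 and extendable(preds[0], cur):
                nxt = preds[0]
                if nxt == oe:  # isolated cycle
                    break
                cur = nxt
                guard += 1
                if guard > len(oriented):
                    break
            else:
                break
        path = [cur]
        seen.add(cur)
        while True:
            succs = graph.successors(path[-1])
            if len(succs) == 1 and extendable(path[-1], succs[0]) and succs[0] not in path:
                path.append(succs[0])
                seen.add(succs[0])
            else:
                break
        unitigs.append(path)
    # keep one strand per unitig (canonically smaller step tuple)
    out: dict[str, GraphPath] = {}
    kept = set()
    idx = 0
    for path in unitigs:
        rc = tuple(flip(s) for s in reversed(path))
        key = min(tuple(path), rc)
        if key in kept:
            continue
        kept.add(key)
        idx += 1
        out[f"NODE_{idx}"] = GraphPath.full(graph, list(key))
    return out


def _contig_map(graph: AssemblyGraph, spec: FixtureSpec, genome_paths: list[GraphPath]):
    if spec.contig_policy == "none":
        return {}
    if spec.contig_policy == "genome":
        return {f"NODE_{i + 1}": p for i, p in enumerate(genome_paths)}
    return unitig_contigs(graph)


def generate_fixture(spec: FixtureSpec, out_dir: str | None = None):
    """Build the fixture graph, contigs, and ground truth.

    Returns (graph, contigs: {name: GraphPath}, truth).  When ``out_dir``
    is given, writes ``graph.gfa``, ``contigs.fasta``, ``contigs.paths``
    and ``truth.json`` there.
    """
    rng = np.random.default_rng(spec.seed)
    k = spec.k
    genes = list(spec.genes)
    n_genes = 2 if spec.tangle and len(genes) < 2 and spec.n_genes < 2 else spec.n_genes
    while len(genes) < n_genes:
        genes.append(random_cds(rng, spec.gene_aa_len))
    for cds in genes:
        _check_cds(cds)

    builder = _Builder(k)
    truth = FixtureTruth()
    genome_paths: list[GraphPath] = []
    coverage: dict[str, float] = {}

    if spec.tangle:
        if len(genes) != 2:
            raise ValueError("tangle fixtures use exactly 2 genes")
        graph, contigs = _build_tangle(builder, rng, spec, genes, truth, genome_paths, coverage)
    else:
        for gi, cds in enumerate(genes):
            _build_linear_gene(builder, rng, spec, cds, gi, truth, genome_paths, coverage)
        graph = builder.build(coverage)
        contigs = _contig_map(graph, spec, genome_paths)
    _resolve_truth(graph, contigs, truth)

    if out_dir is not None:
        _write_fixture(graph, contigs, truth, out_dir)
    return graph, contigs, truth


def _guarded_left_flank(rng, n: int) -> str:
    """Random flank ending with an in-frame stop codon: the upstream
    reading frame of the embedded gene is closed immediately before its
    start codon, making the annotated start the gene's true start."""
    return random_dna(rng, n - 3) + "TAA"


def _build_linear_gene(builder, rng, spec, cds, gi, truth, genome_paths, coverage):
    k = spec.k
    flank_l = _guarded_left_flank(rng, spec.flank)
    flank_r = random_dna(rng, spec.flank)
    genome = flank_l + cds + flank_r
    cds_lo, cds_hi = len(flank_l), len(flank_l) + len(cds)

    # cut points: one per flank, and enough inside the gene for the bubbles;
    # bubble edges alternate with unmodified spacer edges so that serial
    # bubbles are independent (n bubbles -> exactly 2^n alternative paths)
    n_gene_cuts = max(2 * spec.n_bubbles + 1, 2)
    gene_cuts = [
        cds_lo + (i + 1) * len(cds) // (n_gene_cuts + 1) for i in range(n_gene_cuts)
    ]
    cuts = [cds_lo - spec.flank // 2] + gene_cuts + [cds_hi + spec.flank // 2]
    names = builder.tile(genome, cuts)
    for n in names:
        coverage[n] = spec.coverage

    # bubbles: duplicate every other internal gene edge with divergence
    bounds = [0] + sorted(cuts) + [len(genome)]
    internal = [
        i
        for i in range(1, len(bounds) - 2)
        if bounds[i] > cds_lo and bounds[i + 1] < cds_hi
    ]
    chosen = internal[1::2][: spec.n_bubbles]
    if len(chosen) < spec.n_bubbles:
        raise ValueError("gene too short for the requested number of bubbles")
    for i in chosen:
        alt = _mutate_branch(
            rng, genome, bounds[i], bounds[i + 1], (cds_lo, cds_hi),
            spec.bubble_divergence, k,
        )
        if alt is None:
            raise ValueError("could not place a stop-free bubble branch")
        bname = names[i] + "b"
        builder.add_branch(names[i - 1], names[i + 1], alt, bname)
        coverage[bname] = spec.coverage / 2.0

    full = GraphPath(
        [(n, "+") for n in names], 0, len(builder.edges[names[-1]])
    )
    genome_paths.append(full)
    # gene path: slice of the genome path over the CDS span
    truth.genes.append(
        GeneTruth(
            gene_id=f"gene{gi + 1}",
            path=_slice_on_names(builder, names, cds_lo, cds_hi, k),
            nt_seq=cds,
            aa_seq=translate(cds[:-3]),
        )
    )


def _slice_on_names(builder, names, lo, hi, k) -> GraphPath:
    """Path slice over tiled edges covering genome interval [lo, hi)."""
    bounds = []
    cum = 0
    for i, n in enumerate(names):
        seg = len(builder.edges[n]) - (k if i > 0 else 0)
        bounds.append((cum, cum + seg))
        cum += seg
    i1 = next(i for i, (a, b) in enumerate(bounds) if a <= lo < b)
    i2 = next(i for i, (a, b) in enumerate(bounds) if a <= hi - 1 < b)
    off1 = lo - bounds[i1][0] + (k if i1 > 0 else 0)
    off2 = (hi - 1) - bounds[i2][0] + (k if i2 > 0 else 0)
    return GraphPath([(n, "+") for n in names[i1 : i2 + 1]], off1, off2 + 1)


def _build_tangle(builder, rng, spec, genes, truth, genome_paths, coverage):
    """Two gene variants sharing one central repeat edge."""
    k = spec.k
    cds_a = genes[0]
    # variant B: same middle third (the shared repeat), diverged outer thirds
    third = len(cds_a) // 3 // 3 * 3
    mid_lo, mid_hi = third, 2 * third
    cds_b = _diverge_outside(rng, cds_a, mid_lo, mid_hi, rate=0.05)
    repeat = cds_a[mid_lo:mid_hi]
    assert cds_b[mid_lo:mid_hi] == repeat and len(repeat) > k + 10

    names = {}
    for tag, cds in (("a", cds_a), ("b", cds_b)):
        flank_l = _guarded_left_flank(rng, spec.flank)
        flank_r = random_dna(rng, spec.flank)
        genome = flank_l + cds + flank_r
        c_lo = len(flank_l)
        left = genome[: c_lo + mid_lo + k]
        right = genome[c_lo + mid_hi - k :]
        names[tag] = (left, right, genome, c_lo, len(cds))
    rep_id = "R01"
    builder.edges[rep_id] = repeat
    ids = {}
    for tag in ("a", "b"):
        left, right, genome, c_lo, cds_len = names[tag]
        lid, rid = f"L_{tag}", f"S_{tag}"
        builder.edges[lid] = left
        builder.edges[rid] = right
        builder.links += [
            ((lid, "+"), (rep_id, "+")),
            ((rep_id, "+"), (rid, "+")),
        ]
        ids[tag] = (lid, rid)
        for n in (lid, rid):
            coverage[n] = spec.coverage
    coverage[rep_id] = 2 * spec.coverage

    graph = builder.build(coverage)
    for tag, cds in (("a", cds_a), ("b", cds_b)):
        lid, rid = ids[tag]
        _, _, genome, c_lo, cds_len = names[tag]
        steps = [(lid, "+"), (rep_id, "+"), (rid, "+")]
        gp_full = GraphPath.full(graph, steps)
        gene_path = _slice_path(graph, gp_full, c_lo, c_lo + cds_len)
        assert spell(graph, gene_path) == cds
        assert len(gene_path.steps) >= 3
        truth.genes.append(
            GeneTruth(
                gene_id=f"gene_{tag}",
                path=gene_path,
                nt_seq=cds,
                aa_seq=translate(cds[:-3]),
            )
        )
        genome_paths.append(gp_full)
    contigs = _contig_map(graph, spec, genome_paths)
    if spec.contig_policy == "unitigs":
        # tangle promise: no single contig spells a whole gene
        for g in truth.genes:
            for c in contigs.values():
                inner, outer = g.path.steps, c.steps
                assert not _steps_contained(inner, outer)
    return graph, contigs


def _steps_contained(inner, outer) -> bool:
    from .graph import is_step_subpath, flip as _f

    rc = tuple(_f(s) for s in reversed(outer))
    return is_step_subpath(tuple(inner), tuple(outer)) or is_step_subpath(
        tuple(inner), rc
    )


def _diverge_outside(rng, cds, mid_lo, mid_hi, rate):
    """Substitute positions outside [mid_lo, mid_hi) (sparing start and
    stop codons), keeping the frame stop-free."""
    alt = list(cds)
    positions = [
        p for p in range(3, len(cds) - 3) if not mid_lo <= p < mid_hi
    ]
    n_sub = max(1, int(rate * len(positions)))
    for p in sorted(rng.choice(positions, size=n_sub, replace=False)):
        _stop_safe_substitute(rng, alt, 3 * (p // 3), p)
    s = "".join(alt)
    _check_cds(s)
    assert s[mid_lo:mid_hi] == cds[mid_lo:mid_hi]
    return s


def _slice_path(graph: AssemblyGraph, path: GraphPath, lo: int, hi: int) -> GraphPath:
    from .graph import path_slice

    return path_slice(graph, path, lo, hi)


def _resolve_truth(graph, contigs, truth):
    for g in truth.genes:
        assert spell(graph, g.path) == g.nt_seq
        gene_edges = {e for e, _ in g.path.steps}
        g.contigs = sorted(
            name
            for name, p in contigs.items()
            if gene_edges & {e for e, _ in p.steps}
        )


def _write_fixture(graph, contigs, truth, out_dir):
    os.makedirs(out_dir, exist_ok=True)
    write_gfa(graph, os.path.join(out_dir, "graph.gfa"))
    with open(os.path.join(out_dir, "contigs.fasta"), "w") as fa, open(
        os.path.join(out_dir, "contigs.paths"), "w"
    ) as pf:
        for name in sorted(contigs):
            p = contigs[name]
            seq = spell(graph, p)
            fa.write(f">{name}\n{seq}\n")
            pf.write(f"{name}\n")
            pf.write(",".join(f"{e}{o}" for e, o in p.steps) + "\n")
    with open(os.path.join(out_dir, "truth.json"), "w") as fh:
        json.dump(
            {
                g.gene_id: {
                    "path": [f"{e}{o}" for e, o in g.path.steps],
                    "start_offset": g.path.start_offset,
                    "end_offset": g.path.end_offset,
                    "nt_seq": g.nt_seq,
                    "aa_seq": g.aa_seq,
                    "contigs": g.contigs,
                }
                for g in truth.genes
            },
            fh,
            indent=2,
        )


def generate_contig_filter_graph(edge_len_long: int = 400, edge_len_short: int = 200, k: int = 55, seed: int = 97):
    """The branching topology used to illustrate contig-compatibility
    filtering: A -> {B1,B2} -> C -> {D1,D2} -> E, with B1/D1 longer than
    the unique-edge length threshold and B2/D2 shorter.

    Returns (graph, contigs, labeled paths): the contig is the full path
    A,B1,C,D1,E whose unique edges are B1 and D1; the labeled paths are
    ``green`` (the contig itself), ``red`` (B1,C,D2 -- contradicts the
    contig), ``blue`` (A,B2,C,D2 -- shares only non-unique edges) and
    ``yellow`` (C,D1,E -- contained in the contig).
    """
    rng = np.random.default_rng(seed)
    a = random_dna(rng, edge_len_long)
    c = random_dna(rng, edge_len_long)
    e = random_dna(rng, edge_len_long)
    def branch(n, left, right):
        return left[-k:] + random_dna(rng, n - 2 * k) + right[:k]

    edges = {
        "A": a,
        "B1": branch(edge_len_long, a, c),
        "B2": branch(edge_len_short, a, c),
        "C": c,
        "D1": branch(edge_len_long, c, e),
        "D2": branch(edge_len_short, c, e),
        "E": e,
    }
    links = [
        (("A", "+"), ("B1", "+")),
        (("A", "+"), ("B2", "+")),
        (("B1", "+"), ("C", "+")),
        (("B2", "+"), ("C", "+")),
        (("C", "+"), ("D1", "+")),
        (("C", "+"), ("D2", "+")),
        (("D1", "+"), ("E", "+")),
        (("D2", "+"), ("E", "+")),
    ]
    graph = AssemblyGraph(edges, k, links=links)

    def full(steps):
        return GraphPath.full(graph, [(s, "+") for s in steps])

    green = full(["A", "B1", "C", "D1", "E"])
    paths = {
        "green": green,
        "red": full(["B1", "C", "D2"]),
        "blue": full(["A", "B2", "C", "D2"]),
        "yellow": full(["C", "D1", "E"]),
    }
    contigs = {"green_contig": green}
    return graph, contigs, paths
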