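"""Anchor-paths: partial gene hits in the assembly graph.

An anchor-path is the graph image of a local alignment between a known
protein (or profile model) and the spelled sequence of a graph path; it
seeds the search for the complete coding sequence.  Anchors come either
from the built-in brute-force protein-to-graph aligner (intended for
desk-scale graphs) or from an external alignments TSV produced by a
dedicated graph aligner.  Redundant anchors (sub-paths of longer anchors
in the same reading frame) are filtered out before extension.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass

from . import _align
from .graph import (
    AssemblyGraph,
    GraphPath,
    path_slice,
    spell,
    spelled_length,
)

__all__ = [
    "AnchorPath",
    "AnchorThresholds",
    "PathBudgetExceeded",
    "find_anchors_bruteforce",
    "load_external_anchors",
    "filter_subpath_anchors",
]

MIN_ANCHOR_NT = 60  # shorter than any profile model at 90% coverage


@dataclass(frozen=True)
class AnchorPath:
    path: GraphPath
    query_id: str
    query_span: tuple[int, int]  # [start, end) in query residues
    query_len: int
    kind: str = "protein"  # "protein" or "model"
    frame_tag: int = 0  # phase of the path start within its codon
    identity: float = 100.0

    @property
    def fraction_of_query(self) -> float:
        return (self.query_span[1] - self.query_span[0]) / self.query_len

    def key(self) -> tuple:
        return (self.query_id, self.path.key(), self.query_span, self.kind)


@dataclass(frozen=True)
class AnchorThresholds:
    min_protein_fraction: float = 0.8
    min_model_fraction: float = 0.9
    max_evalue: float = 1e-9  # ingested model hits only
    min_identity: float = 80.0  # built-in aligner, % over aligned span

    def __post_init__(self):
        if not (0 < self.min_protein_fraction <= 1 and 0 < self.min_model_fraction <= 1):
            raise ValueError("fractions must lie in (0, 1]")
        if self.max_evalue <= 0:
            raise ValueError("max_evalue must be > 0")


class PathBudgetExceeded(RuntimeError):
    """Graph too tangled for the brute-force aligner; supply external anchors."""


def _maximal_simple_paths(graph: AssemblyGraph, budget: int) -> list[list]:
    """All maximal simple oriented-edge paths, starting from source edges
    (or, in source-free components, from every edge)."""
    oriented = [(e, o) for e in sorted(graph.edges) for o in "+-"]
    sources = [oe for oe in oriented if not graph.predecessors(oe)]
    # components without sources (cycles): fall back to every unreached edge
    reached: set = set()
    frontier = list(sources)
    while frontier:
        oe = frontier.pop()
        if oe in reached:
            continue
        reached.add(oe)
        frontier.extend(graph.successors(oe))
    stack_roots = list(sources) + [oe for oe in oriented if oe not in reached]

    out: list[list] = []
    def extend(path: list, members: set) -> None:
        if len(out) > budget:
            raise PathBudgetExceeded(
                f"more than {budget} maximal paths; use external anchors"
            )
        succ = [s for s in graph.successors(path[-1]) if s not in members]
        if not succ:
            out.append(list(path))
            return
        for s in succ:
            path.append(s)
            members.add(s)
            extend(path, members)
            members.discard(s)
            path.pop()

    for root in stack_roots:
        extend([root], {root})
    # dedupe (cycle fallback may re-walk)
    seen = set()
    uniq = []
    for p in out:
        t = tuple(p)
        if t not in seen:
            seen.add(t)
            uniq.append(p)
    return uniq


def find_anchors_bruteforce(
    graph: AssemblyGraph,
    proteins: dict[str, str],
    thresholds: AnchorThresholds = AnchorThresholds(),
    max_path_len: int = 30000,
    path_budget: int = 20000,
) -> list[AnchorPath]:
    """Six-frame translate every maximal simple-path spelling and locally
    align each query protein against it; hits covering at least
    ``min_protein_fraction`` of the query at ``min_identity`` become
    anchor-paths with coordinates mapped back onto the graph."""
    anchors: dict[tuple, AnchorPath] = {}
    for steps in _maximal_simple_paths(graph, path_budget):
        gp = GraphPath.full(graph, steps)
        seq = spell(graph, gp)[:max_path_len]
        if "N" in seq:
            seq = seq.replace("N", "A")  # neutral filler; hits re-checked by identity
        for frame in range(3):
            sub = seq[frame : frame + 3 * ((len(seq) - frame) // 3)]
            if len(sub) < 3:
                continue
            prot = _align.translate(sub)
            for qid, qseq in sorted(proteins.items()):
                aln = _align.best_local_alignment(qseq, prot)
                if aln is None:
                    continue
                pid, tspan, qspan = _align.alignment_stats(aln)
                if pid < thresholds.min_identity:
                    continue
                if (qspan[1] - qspan[0]) / len(qseq) < thresholds.min_protein_fraction:
                    continue
                nt_start = frame + 3 * tspan[0]
                nt_end = frame + 3 * tspan[1]
                if nt_end - nt_start < MIN_ANCHOR_NT:
                    continue
                apath = path_slice(graph, gp, nt_start, nt_end)
                anchor = AnchorPath(
                    path=apath,
                    query_id=qid,
                    query_span=qspan,
                    query_len=len(qseq),
                    kind="protein",
                    frame_tag=0,
                    identity=pid,
                )
                anchors.setdefault(anchor.key(), anchor)
    return sorted(anchors.values(), key=lambda a: (a.query_id, a.path.key()))


def load_external_anchors(
    path: str,
    graph: AssemblyGraph,
    thresholds: AnchorThresholds = AnchorThresholds(),
) -> list[AnchorPath]:
    """Ingest externally computed anchor alignments.

    TSV columns: query_id, kind (protein|model), query_len, query_start,
    query_end, evalue (or "."), path (comma-separated oriented edge ids),
    start_offset, end_offset.
    """
    out: list[AnchorPath] = []
    with open(path) as fh:
        reader = csv.reader(fh, delimiter="\t")
        for ln, row in enumerate(reader, 1):
            if not row or row[0].startswith("#"):
                continue
            if len(row) != 9:
                raise ValueError(f"row {ln}: expected 9 columns, got {len(row)}")
            qid, kind, qlen, qstart, qend, evalue, pathstr, so, eo = row
            if kind not in ("protein", "model"):
                raise ValueError(f"row {ln}: bad kind {kind!r}")
            qlen, qstart, qend = int(qlen), int(qstart), int(qend)
            steps = []
            for tok in pathstr.split(","):
                tok = tok.strip()
                if tok[-1] not in "+-":
                    raise ValueError(f"row {ln}: malformed step {tok!r}")
                steps.append((tok[:-1], tok[-1]))
            gp = GraphPath(steps, int(so), int(eo))
            for a, b in zip(gp.steps, gp.steps[1:]):
                if b not in graph.successors(a):
                    raise ValueError(f"row {ln}: steps {a}->{b} not in graph adjacency")
            frac = (qend - qstart) / qlen
            if kind == "protein" and frac < thresholds.min_protein_fraction:
                continue
            if kind == "model":
                if frac < thresholds.min_model_fraction:
                    continue
                if evalue != "." and float(evalue) > thresholds.max_evalue:
                    continue
            nt_len = spelled_length(graph, gp)
            if abs(nt_len - 3 * (qend - qstart)) > 2:
                raise ValueError(
                    f"row {ln}: spelled length {nt_len} inconsistent with "
                    f"{qend - qstart} aligned residues"
                )
            if nt_len < MIN_ANCHOR_NT:
                continue
            out.append(
                AnchorPath(
                    path=gp,
                    query_id=qid,
                    query_span=(qstart, qend),
                    query_len=qlen,
                    kind=kind,
                    frame_tag=0,
                )
            )
    return sorted(out, key=lambda a: (a.query_id, a.path.key()))


def _contained_with_frame(
    graph: AssemblyGraph, inner: AnchorPath, outer: AnchorPath
) -> bool:
    """True iff ``inner``'s path (with offsets) lies within ``outer``'s path
    and both read the same frame at the shared positions."""
    a, b = inner.path, outer.path
    n, m = len(a.steps), len(b.steps)
    if n > m:
        return False
    ov = graph.overlap
    for i in range(m - n + 1):
        if b.steps[i : i + n] != a.steps:
            continue
        # spelled offset of a's first base within b
        lo_i = b.start_offset if i == 0 else ov
        if a.start_offset < lo_i:
            continue
        p = a.start_offset - lo_i
        for j in range(i):
            lo_j = b.start_offset if j == 0 else ov
            p += graph.length(b.steps[j][0]) - lo_j
        # a's end must not extend past b's end
        if i + n - 1 == m - 1 and a.end_offset > b.end_offset:
            continue
        if p + spelled_length(graph, a) > spelled_length(graph, b):
            continue
        if inner.frame_tag == (outer.frame_tag + p) % 3:
            return True
    return False


def filter_subpath_anchors(
    anchors: list[AnchorPath], graph: AssemblyGraph
) -> list[AnchorPath]:
    """Drop anchors whose path is contained in another anchor's path in the
    same reading frame; exact duplicates keep one copy."""
    ordered = sorted(anchors, key=lambda a: (a.query_id, a.path.key(), a.kind))
    # dedup exact path duplicates first
    seen_paths: set = set()
    uniq: list[AnchorPath] = []
    for a in ordered:
        k = (a.query_id, a.path.key(), a.kind)
        if k in seen_paths:
            continue
        seen_paths.add(k)
        uniq.append(a)
    kept = []
    for a in uniq:
        redundant = False
        for b in uniq:
            if a is b:
                continue
            if a.path.key() == b.path.key():
                # identical paths across queries: keep both (different evidence)
                continue
            if _contained_with_frame(graph, a, b):
                redundant = True
                break
        if not redundant:
            kept.append(a)
    return sorted(kept, key=lambda a: (a.query_id, a.path.key()))
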