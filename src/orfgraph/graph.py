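"""Bidirected assembly-graph model, GFA 1.0 I/O, and path spelling.

An assembly graph (as emitted by de Bruijn graph assemblers) stores one
nucleotide string per edge; adjacent edges share a fixed number of bases
(the overlap, typically k-1).  Every edge has two faces, ``+`` (the stored
sequence) and ``-`` (its reverse complement); a link ``a+ -> b+`` implies
the symmetric link ``b- -> a-``.  Paths are sequences of oriented edges
with half-open offsets into the first and last edge, and *spell* a
nucleotide string by concatenating oriented edge sequences minus their
shared overlap.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

__all__ = [
    "AssemblyGraph",
    "GraphPath",
    "GFAError",
    "OrientedEdge",
    "Pos",
    "flip",
    "read_gfa",
    "write_gfa",
    "read_contig_paths",
    "read_gfa_paths",
    "spell",
    "reverse_path",
    "revcomp",
    "path_slice",
    "pos_at",
    "is_step_subpath",
    "steps_dovetail",
]

OrientedEdge = tuple[str, str]  # (edge id, "+" or "-")
Pos = tuple[str, str, int]  # (edge id, orientation, 0-based offset into oriented seq)

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def flip(oe: OrientedEdge) -> OrientedEdge:
    return (oe[0], "-" if oe[1] == "+" else "+")


class GFAError(ValueError):
    """Raised on malformed or inconsistent GFA input."""


@dataclass
class AssemblyGraph:
    """Edge-centric bidirected sequence graph.

    Parameters
    ----------
    edges
        Map edge id -> plus-orientation nucleotide string.
    overlap
        Number of bases shared by adjacent edges (>= 0).
    links
        Iterable of (from OrientedEdge, to OrientedEdge) pairs; the
        reverse-complement twin of every link is added automatically.
    coverage
        Optional map edge id -> mean read coverage.
    """

    edges: dict[str, str]
    overlap: int = 0
    coverage: Optional[dict[str, float]] = None
    _adj: dict[OrientedEdge, list[OrientedEdge]] = field(default_factory=dict, repr=False)
    _oriented_cache: dict[OrientedEdge, str] = field(default_factory=dict, repr=False)

    def __init__(
        self,
        edges: dict[str, str],
        overlap: int = 0,
        links: Iterable[tuple[OrientedEdge, OrientedEdge]] = (),
        coverage: Optional[dict[str, float]] = None,
    ):
        self.edges = dict(edges)
        self.overlap = int(overlap)
        self.coverage = dict(coverage) if coverage is not None else None
        self._adj = {}
        self._oriented_cache = {}
        for u, v in links:
            self.add_link(u, v)
        self.validate()

    # -- construction -------------------------------------------------

    def add_link(self, u: OrientedEdge, v: OrientedEdge) -> None:
        for a, b in ((u, v), (flip(v), flip(u))):
            if a[0] not in self.edges or b[0] not in self.edges:
                raise GFAError(f"link {a}->{b} references undeclared segment")
            succ = self._adj.setdefault(a, [])
            if b not in succ:
                succ.append(b)
                succ.sort()

    def validate(self) -> None:
        for eid, seq in self.edges.items():
            if not seq:
                raise GFAError(f"segment {eid} has no sequence")
            if len(seq) <= self.overlap:
                raise GFAError(
                    f"segment {eid} has length {len(seq)} <= overlap {self.overlap}"
                )
            if set(seq.upper()) - set("ACGTN"):
                raise GFAError(f"segment {eid} contains non-ACGTN characters")
        for u, succ in self._adj.items():
            for v in succ:
                if flip(u) not in self._adj.get(flip(v), []):
                    raise GFAError(f"missing reverse-complement link for {u}->{v}")

    # -- queries ------------------------------------------------------

    def successors(self, oe: OrientedEdge) -> list[OrientedEdge]:
        return self._adj.get(oe, [])

    def predecessors(self, oe: OrientedEdge) -> list[OrientedEdge]:
        return sorted(flip(u) for u in self._adj.get(flip(oe), []))

    def links(self) -> Iterator[tuple[OrientedEdge, OrientedEdge]]:
        for u in sorted(self._adj):
            for v in self._adj[u]:
                yield u, v

    def oriented_seq(self, oe: OrientedEdge) -> str:
        s = self._oriented_cache.get(oe)
        if s is None:
            raw = self.edges[oe[0]]
            s = raw if oe[1] == "+" else revcomp(raw)
            self._oriented_cache[oe] = s
        return s

    def length(self, edge_id: str) -> int:
        return len(self.edges[edge_id])

    def base_at(self, pos: Pos) -> str:
        e, o, off = pos
        return self.oriented_seq((e, o))[off]

    def next_positions(self, pos: Pos) -> list[Pos]:
        """Canonical successors of a base position (branching at edge ends)."""
        e, o, off = pos
        if off + 1 < len(self.edges[e]):
            return [(e, o, off + 1)]
        return [(e2, o2, self.overlap) for (e2, o2) in self.successors((e, o))]

    def rc_pos(self, pos: Pos) -> Pos:
        """The same base viewed on the opposite strand."""
        e, o, off = pos
        return (e, "-" if o == "+" else "+", len(self.edges[e]) - 1 - off)

    # node-degree proxies: node identity is implicit, recovered from co-linked edges

    def out_siblings(self, oe: OrientedEdge) -> set[OrientedEdge]:
        """Oriented edges leaving the start node of ``oe`` (including itself)."""
        sibs = {oe}
        for p in self.predecessors(oe):
            sibs.update(self.successors(p))
        return sibs

    def in_siblings(self, oe: OrientedEdge) -> set[OrientedEdge]:
        """Oriented edges entering the end node of ``oe`` (including itself)."""
        sibs = {oe}
        for s in self.successors(oe):
            sibs.update(self.predecessors(s))
        return sibs


@dataclass(frozen=True)
class GraphPath:
    """Ordered oriented edges with half-open offsets into first/last edge."""

    steps: tuple[OrientedEdge, ...]
    start_offset: int
    end_offset: int

    def __init__(self, steps, start_offset: int, end_offset: int):
        object.__setattr__(self, "steps", tuple((e, o) for e, o in steps))
        object.__setattr__(self, "start_offset", int(start_offset))
        object.__setattr__(self, "end_offset", int(end_offset))

    def __len__(self) -> int:
        return len(self.steps)

    def key(self) -> tuple:
        return (self.steps, self.start_offset, self.end_offset)

    @staticmethod
    def full(graph: AssemblyGraph, steps: Iterable[OrientedEdge]) -> "GraphPath":
        steps = [(e, o) for e, o in steps]
        return GraphPath(steps, 0, graph.length(steps[-1][0]))


def _check_connected(graph: AssemblyGraph, path: GraphPath) -> None:
    for a, b in zip(path.steps, path.steps[1:]):
        if b not in graph.successors(a):
            raise ValueError(f"disconnected steps {a} -> {b}")


def normalize_path(graph: AssemblyGraph, path: GraphPath) -> GraphPath:
    """Fold away trailing steps whose contribution lies entirely inside the
    preceding edge's overlap (a multi-step path must end past the overlap
    of its last edge to spell anything on it)."""
    steps = list(path.steps)
    end = path.end_offset
    ov = graph.overlap
    while len(steps) > 1 and end <= ov:
        steps.pop()
        end = graph.length(steps[-1][0]) - ov + end
    return GraphPath(steps, path.start_offset, end)


def spell(graph: AssemblyGraph, path: GraphPath) -> str:
    """Nucleotide string spelled by ``path``.

    The first edge contributes from ``start_offset``; each subsequent edge
    contributes its oriented sequence minus the first ``overlap`` bases;
    the last edge is truncated at ``end_offset`` (exclusive).
    """
    _check_connected(graph, path)
    ov = graph.overlap
    if len(path.steps) > 1 and path.end_offset <= ov:
        raise ValueError(
            "multi-step path ends inside the overlap; normalize_path first"
        )
    if len(path.steps) == 1:
        return graph.oriented_seq(path.steps[0])[path.start_offset : path.end_offset]
    parts = [graph.oriented_seq(path.steps[0])[path.start_offset :]]
    for step in path.steps[1:-1]:
        parts.append(graph.oriented_seq(step)[ov:])
    parts.append(graph.oriented_seq(path.steps[-1])[ov : path.end_offset])
    return "".join(parts)


def spelled_length(graph: AssemblyGraph, path: GraphPath) -> int:
    ov = graph.overlap
    if len(path.steps) == 1:
        return path.end_offset - path.start_offset
    total = graph.length(path.steps[0][0]) - path.start_offset
    for step in path.steps[1:-1]:
        total += graph.length(step[0]) - ov
    total += path.end_offset - ov
    return total


def reverse_path(graph: AssemblyGraph, path: GraphPath) -> GraphPath:
    """The same genomic interval read on the opposite strand."""
    steps = [flip(s) for s in reversed(path.steps)]
    first_len = graph.length(path.steps[-1][0])
    last_len = graph.length(path.steps[0][0])
    rev = GraphPath(steps, first_len - path.end_offset, last_len - path.start_offset)
    return normalize_path(graph, rev)


def pos_at(graph: AssemblyGraph, path: GraphPath, i: int) -> Pos:
    """Base position of the ``i``-th spelled nucleotide of ``path``."""
    if i < 0:
        raise IndexError(i)
    ov = graph.overlap
    cum = 0
    for idx, (e, o) in enumerate(path.steps):
        lo = path.start_offset if idx == 0 else ov
        hi = path.end_offset if idx == len(path.steps) - 1 else graph.length(e)
        n = hi - lo
        if i < cum + n:
            return (e, o, lo + (i - cum))
        cum += n
    raise IndexError(f"position {i} beyond spelled length {cum}")


def path_slice(graph: AssemblyGraph, path: GraphPath, nt_start: int, nt_end: int) -> GraphPath:
    """Sub-path covering spelled interval [nt_start, nt_end)."""
    if not 0 <= nt_start < nt_end:
        raise ValueError((nt_start, nt_end))
    e1, o1, off1 = pos_at(graph, path, nt_start)
    e2, o2, off2 = pos_at(graph, path, nt_end - 1)
    i1 = i2 = None
    cum_end = 0
    # locate the step indices hosting the boundary bases
    ov = graph.overlap
    for idx, (e, o) in enumerate(path.steps):
        lo = path.start_offset if idx == 0 else ov
        hi = path.end_offset if idx == len(path.steps) - 1 else graph.length(e)
        if (e, o) == (e1, o1) and lo <= off1 < hi and i1 is None:
            i1 = idx
        if (e, o) == (e2, o2) and lo <= off2 < hi and (i1 is not None):
            i2 = idx
        cum_end += hi - lo
    if i1 is None or i2 is None:
        raise ValueError("slice boundaries not on path")
    return GraphPath(path.steps[i1 : i2 + 1], off1, off2 + 1)


def equivalent_positions(graph: AssemblyGraph, pos: Pos) -> frozenset:
    """All representations of the same genomic base.

    Bases inside the first ``overlap`` of an edge are shared with every
    predecessor (and symmetrically for the last ``overlap`` bases and
    successors), so one base may have several (edge, orientation, offset)
    names.
    """
    ov = graph.overlap
    seen = {pos}
    queue = [pos]
    while queue:
        e, o, off = queue.pop()
        if off < ov:
            for pe, po in graph.predecessors((e, o)):
                q = (pe, po, graph.length(pe) - ov + off)
                if q not in seen:
                    seen.add(q)
                    queue.append(q)
        if off >= graph.length(e) - ov:
            for se, so in graph.successors((e, o)):
                q = (se, so, off - (graph.length(e) - ov))
                if q not in seen:
                    seen.add(q)
                    queue.append(q)
    return frozenset(seen)


# -- step-level predicates (used by the contig-compatibility filter) ----


def is_step_subpath(inner: tuple[OrientedEdge, ...], outer: tuple[OrientedEdge, ...]) -> bool:
    """True iff ``inner`` occurs as a contiguous run of ``outer``."""
    n, m = len(inner), len(outer)
    if n == 0 or n > m:
        return False
    return any(outer[i : i + n] == inner for i in range(m - n + 1))


def steps_dovetail(a: tuple[OrientedEdge, ...], b: tuple[OrientedEdge, ...]) -> bool:
    """True iff a non-empty suffix of ``a`` equals a prefix of ``b``."""
    for k in range(1, min(len(a), len(b)) + 1):
        if a[-k:] == b[:k]:
            return True
    return False


# -- GFA / contig-path I/O ---------------------------------------------


def _parse_tags(fields: list[str]) -> dict[str, str]:
    tags = {}
    for f in fields:
        parts = f.split(":", 2)
        if len(parts) == 3:
            tags[parts[0]] = parts[2]
    return tags


def read_gfa(path: str) -> AssemblyGraph:
    """Read a GFA 1.0 file (S-lines with sequences, L-lines with a fixed-overlap
    CIGAR like ``55M``); KC/DP tags become per-edge coverage."""
    edges: dict[str, str] = {}
    coverage: dict[str, float] = {}
    raw_links: list[tuple[OrientedEdge, OrientedEdge, int]] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if fields[0] == "S":
                if len(fields) < 3 or fields[2] in ("", "*"):
                    raise GFAError(f"line {ln}: S-line without sequence")
                name, seq = fields[1], fields[2].upper()
                edges[name] = seq
                tags = _parse_tags(fields[3:])
                if "DP" in tags:
                    coverage[name] = float(tags["DP"])
            elif fields[0] == "L":
                if len(fields) < 6:
                    raise GFAError(f"line {ln}: malformed L-line")
                cigar = fields[5]
                if not cigar.endswith("M") or not cigar[:-1].isdigit():
                    raise GFAError(f"line {ln}: unsupported CIGAR {cigar!r}")
                raw_links.append(
                    ((fields[1], fields[2]), (fields[3], fields[4]), int(cigar[:-1]))
                )
    overlaps = {ov for _, _, ov in raw_links}
    if len(overlaps) > 1:
        raise GFAError(f"inconsistent link overlaps: {sorted(overlaps)}")
    overlap = overlaps.pop() if overlaps else 0
    # KC tags count k-mers: coverage = KC / (len - overlap); DP is taken as-is
    with open(path) as fh:
        for line in fh:
            if line.startswith("S\t"):
                fields = line.rstrip("\n").split("\t")
                tags = _parse_tags(fields[3:])
                if "DP" not in tags and "KC" in tags:
                    name, seq = fields[1], fields[2]
                    coverage[name] = float(tags["KC"]) / max(1, len(seq) - overlap)
    return AssemblyGraph(
        edges,
        overlap,
        links=[(u, v) for u, v, _ in raw_links],
        coverage=coverage or None,
    )


def write_gfa(graph: AssemblyGraph, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("H\tVN:Z:1.0\n")
        for eid in sorted(graph.edges):
            tags = ""
            if graph.coverage and eid in graph.coverage:
                tags = f"\tDP:f:{graph.coverage[eid]:g}"
            fh.write(f"S\t{eid}\t{graph.edges[eid]}{tags}\n")
        seen = set()
        for u, v in graph.links():
            if (flip(v), flip(u)) in seen:
                continue
            seen.add((u, v))
            fh.write(f"L\t{u[0]}\t{u[1]}\t{v[0]}\t{v[1]}\t{graph.overlap}M\n")


def _steps_from_string(s: str) -> list[OrientedEdge]:
    steps = []
    for tok in s.split(","):
        tok = tok.strip()
        if not tok:
            continue
        if tok[-1] not in "+-":
            raise GFAError(f"malformed oriented edge {tok!r}")
        steps.append((tok[:-1], tok[-1]))
    return steps


def read_gfa_paths(path: str, graph: AssemblyGraph) -> dict[str, GraphPath]:
    """Contig paths from GFA P-lines."""
    out: dict[str, GraphPath] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("P\t"):
                continue
            fields = line.rstrip("\n").split("\t")
            steps = _steps_from_string(fields[2])
            out[fields[1]] = GraphPath.full(graph, steps)
    return out


def read_contig_paths(path: str, graph: AssemblyGraph) -> dict[str, GraphPath]:
    """SPAdes-style ``.paths`` file: a contig name line followed by one or
    more comma-separated oriented-edge lines; ``;`` marks a gap, and
    gap-containing contig paths are split into gap-free sub-paths."""
    out: dict[str, GraphPath] = {}
    name = None
    chunks: list[str] = []

    def _flush():
        if name is None:
            return
        text = "".join(chunks)
        subpaths = [p for p in text.split(";") if p.strip()]
        for i, sub in enumerate(subpaths):
            steps = _steps_from_string(sub)
            gp = GraphPath.full(graph, steps)
            _check_connected(graph, gp)
            key = name if len(subpaths) == 1 else f"{name}.{i + 1}"
            out[key] = gp

    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            first = line.split(",")[0].rstrip(";")
            looks_like_path = all(
                tok.rstrip(";") == "" or tok.rstrip(";")[-1] in "+-"
                for tok in line.split(",")
            )
            if looks_like_path and name is not None:
                chunks.append(line if line.endswith(";") else line + ";")
                _ = first
            else:
                _flush()
                name = line
                chunks = []
    _flush()
    # drop reverse-complement twins (SPAdes emits NODE_x and NODE_x')
    return {n: p for n, p in out.items() if not n.split(".")[0].endswith("'")}
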