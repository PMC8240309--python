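"""Candidate coding sequences: bounded exhaustive path enumeration between
start codons, anchors and stop codons.

For each (start, stop) pair around an anchor the builder enumerates every
prefix path (start codon -> anchor) and suffix path (anchor -> stop codon)
whose spelled length stays within ``max_restorable_length``, concatenates
them with the anchor, and keeps concatenates that form a clean coding
sequence (start codon, no internal in-frame stop, terminal stop codon).
Enumeration is restricted to edges pre-computed as reachable within the
length budget, generated in breadth-then-lexicographic order, and capped
at ``max_paths_per_pair`` with a truncation flag.  Oriented edges may
repeat along a path (tandem repeats); the length bound, not simplicity,
terminates the search.
"""

from __future__ import annotations

import heapq
from collections import deque
from dataclasses import dataclass, field
from typing import Optional

from . import _align
from .anchors import AnchorPath
from .codons import CodonSite, DEFAULT_START_CODONS, STOP_CODONS
from .graph import (
    AssemblyGraph,
    GraphPath,
    Pos,
    equivalent_positions,
    pos_at,
    spell,
    spelled_length,
)

__all__ = [
    "BuilderLimits",
    "CandidateORF",
    "reachable_edges",
    "enumerate_paths",
    "build_candidates",
    "within_length_limit",
]


@dataclass(frozen=True)
class BuilderLimits:
    max_paths_per_pair: int = 1000
    max_restorable_length: int = 3000

    def __post_init__(self):
        if self.max_paths_per_pair <= 0 or self.max_restorable_length <= 0:
            raise ValueError("limits must be positive")


def within_length_limit(nt_len: int, limits: BuilderLimits) -> bool:
    """Concatenate length check: kept iff <= max_restorable_length."""
    return nt_len <= limits.max_restorable_length


@dataclass
class CandidateORF:
    """A complete coding path from start codon through stop codon."""

    path: GraphPath
    nt_seq: str
    aa_seq: str
    source_anchor: AnchorPath
    start_site: CodonSite
    stop_site: CodonSite
    triplet: tuple[float, float, int] = (1.0, 0.0, 0)
    flags: frozenset = field(default_factory=frozenset)
    orf_id: str = ""
    verdict: str = ""
    best_hit: str = ""
    best_identity: float = 0.0


def _end_reps(graph: AssemblyGraph, w: Pos) -> list[tuple[str, str, int]]:
    """Equivalent (edge, orient, exclusive-end-offset) representations of an
    exclusive path end: bases inside edge overlaps have one name per
    adjacent edge, and a path may finish at any of them."""
    end_base = (w[0], w[1], w[2] - 1)
    return sorted(
        (e, o, off + 1) for e, o, off in equivalent_positions(graph, end_base)
    )


def reachable_edges(
    graph: AssemblyGraph, v: Pos, w: Pos, max_len: int
) -> set[tuple[str, str]]:
    """Oriented edges lying on at least one v->w path of spelled length
    <= ``max_len`` (exclusive end ``w``); exact via forward/backward
    shortest distances (repeats allowed, so min-forward + min-backward
    concatenations are realizable paths)."""
    ov = graph.overlap
    v_reps = sorted(equivalent_positions(graph, v))
    result: set[tuple[str, str]] = set()
    for we, wo, woff in _end_reps(graph, w):
        # single-step case (same edge, forward span)
        for ve, vo, voff in v_reps:
            if (ve, vo) == (we, wo) and 0 < woff - voff <= max_len:
                result.add((ve, vo))
        # forward Dijkstra: f(e) = min spelled length from v through end of e
        f: dict[tuple[str, str], int] = {}
        heap = [(graph.length(ve) - voff, (ve, vo)) for ve, vo, voff in v_reps]
        heapq.heapify(heap)
        while heap:
            d, oe = heapq.heappop(heap)
            if oe in f:
                continue
            f[oe] = d
            if d > max_len + graph.length(oe[0]):
                continue
            for s in graph.successors(oe):
                if s not in f:
                    heapq.heappush(heap, (d + graph.length(s[0]) - ov, s))
        # backward Dijkstra: g(e) = min spelled length contributed after e
        g: dict[tuple[str, str], int] = {}
        start_g = woff - graph.length(we)
        heap = [(start_g, (we, wo))]
        while heap:
            d, oe = heapq.heappop(heap)
            if oe in g:
                continue
            g[oe] = d
            if d > max_len:
                continue
            for p in graph.predecessors(oe):
                if p not in g:
                    heapq.heappush(heap, (d + graph.length(oe[0]) - ov, p))
        for oe, fd in f.items():
            gd = g.get(oe)
            if gd is None:
                continue
            total = fd + gd
            # multi-step paths need the end to land past the overlap
            if total > 0 and total <= max_len:
                # a landing inside the leading overlap is non-canonical for
                # the landing edge itself (single-step spans handled above)
                if oe == (we, wo) and gd == start_g and woff <= ov:
                    continue
                result.add(oe)
    return result


def enumerate_paths(
    graph: AssemblyGraph,
    v: Pos,
    w: Pos,
    limits: BuilderLimits = BuilderLimits(),
    edge_whitelist: Optional[set] = None,
    max_len: Optional[int] = None,
) -> tuple[list[GraphPath], bool]:
    """All v->w paths (``v`` inclusive, ``w`` exclusive) of spelled length
    <= ``max_len`` (default ``max_restorable_length``), in breadth-then-
    lexicographic order, truncated at ``max_paths_per_pair``.

    Returns (paths, truncated).
    """
    if max_len is None:
        max_len = limits.max_restorable_length
    ov = graph.overlap
    reps: dict[tuple[str, str], list[int]] = {}
    for we, wo, woff in _end_reps(graph, w):
        reps.setdefault((we, wo), []).append(woff)
    out: list[GraphPath] = []
    emitted: set = set()
    truncated = False
    # nodes are (parent, oriented_edge, length_through_end_of_edge, root_offset);
    # the start base may have one representation per edge sharing it
    queue = deque(
        (None, (ve, vo), graph.length(ve) - voff, voff)
        for ve, vo, voff in sorted(equivalent_positions(graph, v))
    )
    while queue:
        node = queue.popleft()
        parent, oe, F, voff = node
        single = parent is None
        for woff in sorted(reps.get(oe, [])):
            if single:
                L = woff - voff
                valid = L > 0
            else:
                L = F - (graph.length(oe[0]) - woff)
                valid = woff > ov and L > 0
            if valid and L <= max_len:
                steps = []
                n = node
                while n is not None:
                    steps.append(n[1])
                    n = n[0]
                steps.reverse()
                gp = GraphPath(steps, voff, woff)
                if gp.key() in emitted:
                    continue
                if len(out) >= limits.max_paths_per_pair:
                    truncated = True
                    queue.clear()
                    break
                emitted.add(gp.key())
                out.append(gp)
        if truncated:
            break
        if F >= max_len:
            continue  # any extension would exceed the bound
        for s in graph.successors(oe):
            if edge_whitelist is not None and s not in edge_whitelist:
                continue
            queue.append((node, s, F + graph.length(s[0]) - ov, voff))
    return out, truncated


def _join(graph: AssemblyGraph, p: GraphPath, q: GraphPath, shared: int) -> GraphPath:
    """Concatenate paths overlapping by ``shared`` spelled bases.

    ``q``'s first ``shared`` bases coincide with ``p``'s last ``shared``;
    the merged path is validated by re-spelling.
    """
    expect = spell(graph, p) + spell(graph, q)[shared:]
    ov = graph.overlap
    candidates = []
    if q.steps[0] == p.steps[-1] and q.start_offset == p.end_offset - shared:
        if len(q.steps) == 1:
            candidates.append(GraphPath(p.steps, p.start_offset, q.end_offset))
        else:
            candidates.append(
                GraphPath(p.steps + q.steps[1:], p.start_offset, q.end_offset)
            )
    if p.steps[-1] in graph.predecessors(q.steps[0]):
        # p's spelled end falls inside the overlap shared with q's first edge;
        # the re-spelling check below arbitrates
        candidates.append(GraphPath(p.steps + q.steps, p.start_offset, q.end_offset))
    for merged in candidates:
        try:
            if spell(graph, merged) == expect:
                return merged
        except ValueError:
            continue
    raise ValueError("paths do not abut")


def build_candidates(
    anchor: AnchorPath,
    starts: list[CodonSite],
    stops: list[CodonSite],
    graph: AssemblyGraph,
    limits: BuilderLimits = BuilderLimits(),
    start_codons: frozenset = DEFAULT_START_CODONS,
) -> list[CandidateORF]:
    """Assemble complete coding paths for every (start, stop) pair.

    Concatenates each prefix x suffix with the anchor, drops concatenates
    exceeding the length limit or violating coding invariants, and
    deduplicates on the translated amino-acid sequence.
    """
    alen = spelled_length(graph, anchor.path)
    anchor_first = pos_at(graph, anchor.path, 0)
    anchor_last = pos_at(graph, anchor.path, alen - 1)
    by_aa: dict[str, CandidateORF] = {}
    for start in sorted(starts, key=CodonSite.sort_key):
        if start.distance == 0 and anchor_first in equivalent_positions(
            graph, start.position
        ):
            prefixes = [None]
            pref_trunc = False
        else:
            fe, fo, foff = anchor_first
            w = (fe, fo, foff + 1)  # include the anchor's first base
            wl = reachable_edges(graph, start.position, w, limits.max_restorable_length)
            prefixes, pref_trunc = enumerate_paths(
                graph, start.position, w, limits, edge_whitelist=wl
            )
        for stop in sorted(stops, key=CodonSite.sort_key):
            le, lo, loff = stop.last_pos
            w = (le, lo, loff + 1)
            wl = reachable_edges(graph, anchor_last, w, limits.max_restorable_length)
            suffixes, suf_trunc = enumerate_paths(
                graph, anchor_last, w, limits, edge_whitelist=wl
            )
            pair_truncated = pref_trunc or suf_trunc
            for pre in prefixes:
                try:
                    left = anchor.path if pre is None else _join(graph, pre, anchor.path, 1)
                except ValueError:
                    continue
                for suf in suffixes:
                    try:
                        full = _join(graph, left, suf, 1)
                    except ValueError:
                        continue
                    nt = spell(graph, full)
                    if not within_length_limit(len(nt), limits):
                        continue
                    if len(nt) % 3 != 0 or "N" in nt:
                        continue
                    if nt[:3] not in start_codons or nt[-3:] not in STOP_CODONS:
                        continue
                    codons = [nt[i : i + 3] for i in range(0, len(nt) - 3, 3)]
                    if any(c in STOP_CODONS for c in codons):
                        continue
                    aa = _align.translate(nt[:-3])
                    flags = set(start.flags)
                    if pair_truncated:
                        flags.add("truncated-enumeration")
                    orf = CandidateORF(
                        path=full,
                        nt_seq=nt,
                        aa_seq=aa,
                        source_anchor=anchor,
                        start_site=start,
                        stop_site=stop,
                        flags=frozenset(flags),
                    )
                    if aa not in by_aa:
                        by_aa[aa] = orf
    return sorted(by_aa.values(), key=lambda o: (o.start_site.sort_key(), o.stop_site.sort_key(), o.path.key()))
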