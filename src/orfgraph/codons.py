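"""Start/stop-codon search around anchor-paths.

From the right end of an anchor the graph is explored forward by a
breadth-first search that carries a *frameshift string* -- the 1-3 nt of
the partially consumed codon -- across edge boundaries.  A state whose
frameshift string completes a stop codon is terminal and is not expanded
further (no reading frame extends through an in-frame stop).  The start
side runs the same machinery on the reverse-complement view of the graph:
moving upstream on the forward strand is moving forward on the opposite
strand, and a forward start codon appears as its reverse complement.
Upstream exploration is *not* pruned at in-frame stops; starts lying
beyond one are flagged ``after-stop`` instead, and starts preceded by a
Shine-Dalgarno-like motif are flagged ``has-sd``.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

from .graph import (
    AssemblyGraph,
    Pos,
    equivalent_positions,
    pos_at,
    revcomp,
    spelled_length,
)
from .anchors import AnchorPath

__all__ = [
    "CodonSite",
    "DEFAULT_START_CODONS",
    "STOP_CODONS",
    "find_start_codons",
    "find_stop_codons",
]

DEFAULT_START_CODONS = frozenset({"ATG", "GTG", "TTG"})
STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

SD_MOTIF = "AGGAGG"
SD_MIN_MATCHES = 4
SD_GAP_RANGE = (5, 15)  # nt between motif end and the start codon


@dataclass(frozen=True)
class CodonSite:
    """An in-frame start or stop codon reachable from an anchor boundary.

    ``position`` is the forward-strand location of the codon's first base;
    ``last_pos`` that of its third base.  ``distance`` counts nucleotides
    between the anchor's in-frame boundary and the codon's near end and is
    always a multiple of 3.
    """

    position: Pos
    last_pos: Pos
    codon: str
    kind: str  # "start" | "stop"
    distance: int
    flags: frozenset = field(default_factory=frozenset)

    def sort_key(self) -> tuple:
        return (self.distance, self.position, self.codon)


def _codon_bfs(graph, init, max_dist, targets, terminal):
    """BFS over (position, consumed-in-codon, buffer) states.

    ``init`` is a list of (pos, codon_start_distance) pairs where ``pos``
    begins a fresh codon.  Returns {(first_pos, last_pos, codon): distance}.
    (The same first base can begin several distinct codons when the second
    or third base lies past a branch point, so both endpoints key a hit.)
    When ``terminal`` is true, states completing a target codon are not
    expanded (stop-codon semantics); otherwise exploration continues
    through target codons (start-codon semantics).
    """
    found: dict[tuple, int] = {}
    queue = deque()
    for pos, d in init:
        queue.append((pos, "", pos, d))
    visited = set()
    while queue:
        pos, buf, cstart, cdist = queue.popleft()
        if cdist > max_dist:
            continue
        key = (pos, len(buf), buf)
        if key in visited:
            continue
        visited.add(key)
        base = graph.base_at(pos)
        if base == "N":
            continue  # cannot call codons through unresolved bases
        if len(buf) == 2:
            codon = buf + base
            hit = codon in targets
            if hit:
                k = (cstart, pos, codon)
                if k not in found:
                    found[k] = cdist
            if hit and terminal:
                continue
            for nxt in graph.next_positions(pos):
                queue.append((nxt, "", nxt, cdist + 3))
        else:
            for nxt in graph.next_positions(pos):
                queue.append((nxt, buf + base, cstart, cdist))
    return found


def _advance(graph, positions: list[Pos], n: int) -> list[tuple[Pos, int]]:
    """All positions reachable by consuming exactly ``n`` bases, paired with 0."""
    cur = positions
    for _ in range(n):
        nxt = []
        seen = set()
        for p in cur:
            for q in graph.next_positions(p):
                if q not in seen:
                    seen.add(q)
                    nxt.append(q)
        cur = nxt
    return [(p, 0) for p in cur]


def find_stop_codons(
    graph: AssemblyGraph, anchor: AnchorPath, max_dist: int
) -> list[CodonSite]:
    """All distinct in-frame stop codons reachable downstream of the anchor
    within ``max_dist`` nt; exploration stops at each stop found."""
    if max_dist < 0:
        raise ValueError("max_dist must be >= 0")
    alen = spelled_length(graph, anchor.path)
    phase_end = (anchor.frame_tag + alen) % 3
    skip = (3 - phase_end) % 3  # bases to the first codon boundary after the anchor
    last_base = pos_at(graph, anchor.path, alen - 1)
    # the boundary base may sit inside an edge overlap: seed every
    # representation so sibling-edge continuations are not missed
    init = _advance(
        graph, sorted(equivalent_positions(graph, last_base)), 1 + skip
    )
    found = _codon_bfs(graph, init, max_dist, STOP_CODONS, terminal=True)
    # one site per physical codon: overlap-duplicated representations merge
    merged: dict[tuple, int] = {}
    for (cstart, lp, codon), d in found.items():
        key = (
            min(equivalent_positions(graph, cstart)),
            min(equivalent_positions(graph, lp)),
            codon,
        )
        if key not in merged or merged[key] > d:
            merged[key] = d
    sites = [
        CodonSite(position=cpos, last_pos=lp, codon=codon, kind="stop", distance=d)
        for (cpos, lp, codon), d in merged.items()
    ]
    return sorted(sites, key=CodonSite.sort_key)


def _rc_set(codons) -> frozenset:
    return frozenset(revcomp(c) for c in codons)


def _has_upstream_stop(graph, rc_after_start: list[Pos], budget: int) -> bool:
    """Is any in-frame stop reachable continuing upstream past a start?"""
    if budget < 0:
        return False
    init = [(p, 0) for p in rc_after_start]
    found = _codon_bfs(graph, init, budget, _rc_set(STOP_CODONS), terminal=True)
    return bool(found)


def _upstream_strings(graph, roots: list[Pos], length: int) -> list[str]:
    """Spelled strings (reverse-complement reading) of all paths of up to
    ``length`` bases starting at ``roots``; bounded exhaustive DFS."""
    out: list[str] = []

    def walk(pos: Pos, acc: list[str]) -> None:
        acc.append(graph.base_at(pos))
        if len(acc) >= length:
            out.append("".join(acc))
        else:
            nxts = graph.next_positions(pos)
            if not nxts:
                out.append("".join(acc))
            for nxt in nxts:
                walk(nxt, acc)
        acc.pop()

    for r in roots:
        walk(r, [])
    return out


def _has_sd_motif(graph, rc_after_start: list[Pos]) -> bool:
    lo, hi = SD_GAP_RANGE
    rc_motif = revcomp(SD_MOTIF)
    need = hi + len(SD_MOTIF)
    for s in _upstream_strings(graph, rc_after_start, need):
        for g in range(lo, hi + 1):
            win = s[g : g + len(SD_MOTIF)]
            if len(win) < len(SD_MOTIF):
                break
            matches = sum(a == b for a, b in zip(win, rc_motif))
            if matches >= SD_MIN_MATCHES:
                return True
    return False


def find_start_codons(
    graph: AssemblyGraph,
    anchor: AnchorPath,
    max_dist: int,
    start_codons: frozenset = DEFAULT_START_CODONS,
) -> list[CodonSite]:
    """All distinct in-frame start codons at or upstream of the anchor's left
    boundary within ``max_dist`` nt (distance 0 = the anchor's own first
    codon).  Exploration is not pruned at upstream stops; starts beyond one
    carry the ``after-stop`` flag, and a Shine-Dalgarno-like motif 5-15 nt
    upstream sets ``has-sd``."""
    if max_dist < 0:
        raise ValueError("max_dist must be >= 0")
    t = anchor.frame_tag % 3
    merged: dict[tuple, int] = {}
    first_base = pos_at(graph, anchor.path, 0)
    if t == 0:
        # the anchor's own first codon is read off the anchor path itself
        # (retracing it through the graph could wander onto sibling edges
        # sharing the boundary overlap but not containing the anchor)
        codon0 = "".join(
            graph.base_at(pos_at(graph, anchor.path, i)) for i in range(3)
        )
        if codon0 in start_codons:
            key0 = (
                min(equivalent_positions(graph, first_base)),
                min(equivalent_positions(graph, pos_at(graph, anchor.path, 2))),
                codon0,
            )
            merged[key0] = 0
    # BFS over fresh codons strictly upstream of the anchor's first base;
    # every overlap representation of that base seeds its own continuations.
    # For boundary phase t != 0 the codon spanning the boundary is skipped
    # and scanning begins at the first fully upstream in-frame codon.
    roots = []
    seen = set()
    for rep in sorted(equivalent_positions(graph, first_base)):
        for nxt in graph.next_positions(graph.rc_pos(rep)):
            if nxt not in seen:
                seen.add(nxt)
                roots.append(nxt)
    if t:
        roots = [p for p, _ in _advance(graph, roots, t)]
    init = [(p, 3) for p in roots]
    found = _codon_bfs(
        graph, init, max_dist, _rc_set(start_codons), terminal=False
    )
    # merge overlap-duplicated representations of the same physical codon
    for (rc_cstart, rc_lastpos, rc_codon), d in found.items():
        first = min(equivalent_positions(graph, graph.rc_pos(rc_lastpos)))
        last = min(equivalent_positions(graph, graph.rc_pos(rc_cstart)))
        key = (first, last, revcomp(rc_codon))
        if key not in merged or merged[key] > d:
            merged[key] = d
    sites = []
    for (first, last, codon), d in merged.items():
        # continue upstream from every representation of the base before
        # the codon (sibling edges share the overlap bases)
        beyond = []
        for rc_first in equivalent_positions(graph, graph.rc_pos(first)):
            for nxt in graph.next_positions(rc_first):
                if nxt not in beyond:
                    beyond.append(nxt)
        beyond.sort()
        flags = set()
        if _has_upstream_stop(graph, beyond, max_dist - d - 3):
            flags.add("after-stop")
        if _has_sd_motif(graph, beyond):
            flags.add("has-sd")
        sites.append(
            CodonSite(
                position=first,
                last_pos=last,
                codon=codon,
                kind="start",
                distance=d,
                flags=frozenset(flags),
            )
        )
    return sorted(sites, key=CodonSite.sort_key)
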