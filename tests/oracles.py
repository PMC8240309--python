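"""Independent brute-force oracles used by the test suite.

These deliberately avoid the library's BFS/Dijkstra machinery: codon
sites are found by enumerating every base-level path and scanning codons
in frame; path sets by exhaustive recursion.  They are only feasible on
tiny graphs, which is the point.
"""

from __future__ import annotations

import numpy as np

from orfgraph.graph import AssemblyGraph, GraphPath, Pos, equivalent_positions, pos_at, spelled_length
from orfgraph.codons import STOP_CODONS


def canonical_pos(graph: AssemblyGraph, pos: Pos) -> Pos:
    return min(equivalent_positions(graph, pos))


def site_map(graph, sites):
    """{(canonical first-base pos, codon): min distance} for CodonSites;
    several distinct codons may share a first base past a branch point."""
    out: dict = {}
    for s in sites:
        k = (canonical_pos(graph, s.position), s.codon)
        if k not in out or out[k] > s.distance:
            out[k] = s.distance
    return out


def _next(graph, pos):
    e, o, off = pos
    if off + 1 < graph.length(e):
        return [(e, o, off + 1)]
    return [(s, so, graph.overlap) for s, so in graph.successors((e, o))]


def _prev(graph, pos):
    e, o, off = pos
    if off > 0:
        return [(e, o, off - 1)]
    return [
        (p, po, graph.length(p) - graph.overlap - 1)
        for p, po in graph.predecessors((e, o))
    ]


def _next_classes(graph, pos):
    """Canonical classes of the base(s) following ``pos``; branches at
    junctions are found through every overlap representation."""
    out = set()
    for e, o, off in equivalent_positions(graph, pos):
        if off + 1 < graph.length(e):
            out.add(canonical_pos(graph, (e, o, off + 1)))
        else:
            for s, so in graph.successors((e, o)):
                out.add(canonical_pos(graph, (s, so, graph.overlap)))
    return sorted(out)


def _prev_classes(graph, pos):
    out = set()
    for e, o, off in equivalent_positions(graph, pos):
        if off > 0:
            out.add(canonical_pos(graph, (e, o, off - 1)))
        elif graph.overlap == 0:
            for p, po in graph.predecessors((e, o)):
                out.add(canonical_pos(graph, (p, po, graph.length(p) - 1)))
    return sorted(out)


def brute_stop_sites(graph, anchor, max_dist):
    """{(canonical first-base pos, codon): min distance} by enumerating all
    forward base paths; each path contributes its first in-frame stop."""
    alen = spelled_length(graph, anchor.path)
    start_positions = _next_classes(graph, pos_at(graph, anchor.path, alen - 1))
    found: dict = {}

    def walk(pos, dist, buf, cstart):
        base = graph.base_at(pos)
        if base == "N":
            return
        if len(buf) == 2:
            codon = buf + base
            if codon in STOP_CODONS:
                if dist <= max_dist:
                    key = (canonical_pos(graph, cstart), codon)
                    if key not in found or found[key] > dist:
                        found[key] = dist
                return  # first stop terminates this path
            if dist + 3 > max_dist:
                return
            for nxt in _next_classes(graph, pos):
                walk(nxt, dist + 3, "", nxt)
        else:
            for nxt in _next_classes(graph, pos):
                walk(nxt, dist, buf + base, cstart)

    for p in start_positions:
        walk(p, 0, "", p)
    return found


def brute_start_sites(graph, anchor, max_dist, start_codons):
    """{(canonical first-base pos, codon): min distance} for in-frame start
    codons at or upstream of the anchor (distance 0 = the anchor's own
    first codon), by enumerating backward base paths."""
    found: dict = {}
    first3 = [pos_at(graph, anchor.path, i) for i in range(3)]

    def record(codon_positions, dist):
        codon = "".join(graph.base_at(p) for p in codon_positions)
        if codon in start_codons and dist <= max_dist:
            key = (canonical_pos(graph, codon_positions[0]), codon)
            if key not in found or found[key] > dist:
                found[key] = dist

    record(first3, 0)

    def walk(pos, back_steps, trail):
        """trail[i] = position back_steps-i bases upstream of the anchor."""
        trail = trail + [pos]
        if back_steps % 3 == 0:
            d = back_steps
            if d <= max_dist and len(trail) >= 3:
                record([trail[-1], trail[-2], trail[-3]], d)
        if back_steps >= max_dist:
            return
        for prv in _prev_classes(graph, pos):
            walk(prv, back_steps + 1, trail)

    # walk upstream; trail grows from anchor outwards; codon at distance d
    # occupies the bases d, d-1, d-2 upstream of the anchor start
    for prv in _prev_classes(graph, pos_at(graph, anchor.path, 0)):
        walk(prv, 1, [])
    return found


def brute_enumerate_paths(graph, v, w, max_len):
    """All v->w paths (v inclusive, w exclusive) up to max_len, as base
    position lists; exhaustive recursion over bases.  Both endpoints may
    carry several overlap-duplicated representations; all are explored."""
    out = []
    target_ends = equivalent_positions(graph, (w[0], w[1], w[2] - 1))

    def walk(pos, chain):
        chain = chain + [pos]
        if len(chain) > max_len:
            return
        if pos in target_ends:
            out.append(list(chain))
        for nxt in _next(graph, pos):
            walk(nxt, chain)

    for rep in sorted(equivalent_positions(graph, v)):
        walk(rep, [])
    return out


def base_chain_to_steps(graph, chain):
    """Collapse a base-position list into an oriented-edge step tuple."""
    steps = [chain[0][:2]]
    for pos in chain[1:]:
        if pos[:2] != steps[-1]:
            steps.append(pos[:2])
    return tuple(steps)


def random_consistent_graph(
    rng: np.random.Generator,
    n_junctions: int = 5,
    n_edges: int = 8,
    overlap: int = 3,
    max_mid: int = 20,
) -> AssemblyGraph:
    """Random overlap-consistent DAG: junction nodes carry random
    ``overlap``-mers; each edge spells start-junction + middle + end-junction,
    so all linked edges genuinely share their overlap bases."""
    bases = list("ACGT")
    junctions = ["".join(rng.choice(bases, size=overlap)) for _ in range(n_junctions)]
    edges = {}
    ends = {}
    for i in range(n_edges):
        u = int(rng.integers(0, n_junctions - 1))
        v = int(rng.integers(u + 1, n_junctions))
        mid = "".join(rng.choice(bases, size=int(rng.integers(1, max_mid))))
        name = f"e{i}"
        edges[name] = junctions[u] + mid + junctions[v]
        ends[name] = (u, v)
    links = []
    for a, (ua, va) in ends.items():
        for b, (ub, vb) in ends.items():
            if va == ub:
                links.append(((a, "+"), (b, "+")))
    return AssemblyGraph(edges, overlap, links=links)


def random_anchor(graph: AssemblyGraph, rng: np.random.Generator):
    """A codon-aligned anchor on a random edge path of the graph."""
    from orfgraph.anchors import AnchorPath
    from orfgraph.graph import path_slice, spell

    oriented = sorted((e, "+") for e in graph.edges)
    start = oriented[int(rng.integers(0, len(oriented)))]
    steps = [start]
    while rng.random() < 0.7:
        succ = graph.successors(steps[-1])
        succ = [s for s in succ if s not in steps]
        if not succ:
            break
        steps.append(succ[int(rng.integers(0, len(succ)))])
    gp = GraphPath.full(graph, steps)
    total = spelled_length(graph, gp)
    if total < 9:
        return None
    aa = min(total // 3, 4 + int(rng.integers(0, 5)))
    lo_max = total - 3 * aa
    lo = int(rng.integers(0, lo_max + 1))
    sub = path_slice(graph, gp, lo, lo + 3 * aa)
    return AnchorPath(
        path=sub, query_id="q", query_span=(0, aa), query_len=aa, frame_tag=0
    )
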