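"""Single-linkage clustering of candidate ORFs and representative selection.

Two predicted proteins belong to the same cluster if one is a substring
of the other or their percent identity exceeds PI (default 90%); clusters
are the connected components of that relation.  Within a cluster, members
are ranked by the lexicographic order of their reliability triplet
(start-distance likelihood, read coverage, path length), and a greedy
scan keeps a member as representative whenever it contains a long
(> 1 kb) cluster edge not covered by previously kept members, so that
every long cluster edge appears in at least one representative.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from ._align import identity_to_shorter
from .cds import CandidateORF
from .graph import AssemblyGraph

__all__ = [
    "Cluster",
    "ClusterParams",
    "cluster_orfs",
    "rank_triplet",
    "select_representatives",
]


@dataclass(frozen=True)
class ClusterParams:
    percent_identity: float = 90.0  # PI
    long_edge_min: int = 1000

    def __post_init__(self):
        if not 0 < self.percent_identity <= 100:
            raise ValueError("PI must lie in (0, 100]")


@dataclass
class Cluster:
    members: list[CandidateORF]
    long_cluster_edges: set[str] = field(default_factory=set)
    representatives: list[CandidateORF] = field(default_factory=list)


def rank_triplet(orf: CandidateORF) -> tuple[float, float, int]:
    """(start-distance likelihood, read coverage, path length); compared
    lexicographically, larger = more reliable."""
    return orf.triplet


def _related(a: CandidateORF, b: CandidateORF, pi: float) -> bool:
    sa, sb = a.aa_seq, b.aa_seq
    if sa in sb or sb in sa:
        return True
    return identity_to_shorter(sa, sb) > pi


def cluster_orfs(
    orfs: list[CandidateORF],
    params: ClusterParams = ClusterParams(),
    graph: AssemblyGraph | None = None,
) -> list[Cluster]:
    """Connected components of the substring-or-identity relation; member
    and cluster order is canonical (by ORF id) so the output does not
    depend on input order.  When ``graph`` is given, each cluster's long
    cluster edges (> ``long_edge_min`` nt) are filled in."""
    ordered = sorted(orfs, key=lambda o: (o.orf_id, o.aa_seq))
    n = len(ordered)
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x: int, y: int) -> None:
        rx, ry = find(x), find(y)
        if rx != ry:
            parent[max(rx, ry)] = min(rx, ry)

    for i in range(n):
        for j in range(i + 1, n):
            if _related(ordered[i], ordered[j], params.percent_identity):
                union(i, j)

    groups: dict[int, list[CandidateORF]] = {}
    for i, orf in enumerate(ordered):
        groups.setdefault(find(i), []).append(orf)
    clusters = []
    for root in sorted(groups):
        members = groups[root]
        c = Cluster(members=members)
        if graph is not None:
            c.long_cluster_edges = {
                e
                for orf in members
                for e, _ in orf.path.steps
                if graph.length(e) > params.long_edge_min
            }
        clusters.append(c)
    return clusters


def select_representatives(
    cluster: Cluster,
    graph: AssemblyGraph,
    params: ClusterParams = ClusterParams(),
    scan_order: str = "descending",
) -> list[CandidateORF]:
    """Greedy cover of the cluster's long edges by its most reliable members.

    Members are scanned from lexicographically largest triplet to smallest
    (``scan_order="ascending"`` restores the literal least-reliable-first
    order); a member is kept iff it contains a long cluster edge not yet
    covered.  A cluster without long edges keeps its single most reliable
    member.
    """
    if not cluster.members:
        raise ValueError("empty cluster")
    long_edges = {
        e
        for orf in cluster.members
        for e, _ in orf.path.steps
        if graph.length(e) > params.long_edge_min
    }
    cluster.long_cluster_edges = long_edges
    if scan_order == "descending":
        def key(o):
            t = rank_triplet(o)
            return ((-t[0], -t[1], -t[2]), o.orf_id)
    else:
        def key(o):
            return (rank_triplet(o), o.orf_id)
    ordered = sorted(cluster.members, key=key)
    if not long_edges:
        def best_key(o):
            t = rank_triplet(o)
            return ((-t[0], -t[1], -t[2]), o.orf_id)
        cluster.representatives = [min(cluster.members, key=best_key)]
        return cluster.representatives
    reps: list[CandidateORF] = []
    covered: set[str] = set()
    for orf in ordered:
        mine = {e for e, _ in orf.path.steps} & long_edges
        if mine - covered:
            reps.append(orf)
            covered |= mine
    cluster.representatives = reps
    assert covered == long_edges
    return reps
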