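"""Single-linkage clustering and representative selection."""

from itertools import combinations, permutations

from conftest import make_orf
from orfgraph.clustering import (
    cluster_orfs,
    rank_triplet,
    select_representatives,
)
from orfgraph.graph import AssemblyGraph, GraphPath

BASE = (
    "MKVLAATGRESLDKVNQLIEDFSGKAPQWVRENAYHLIKEAGLDTPEQVVREAMKQLQ"
    "PDEVKRLGEYSARTMWDKLTPEERAAFDEKAQALIAEYGLSNPDKVNELAGKWGLDTP"
) * 2


def _mutate(seq, n, alt="W", phase=0):
    out = list(seq)
    for i in range(n):
        pos = ((i * len(seq)) // n + phase) % len(seq)
        out[pos] = alt if out[pos] != alt else "Y"
    return "".join(out)


class TestClustering:
    def test_substring_rule(self):
        a = make_orf(BASE, orf_id="a")
        b = make_orf(BASE[10:100], orf_id="b")
        clusters = cluster_orfs([a, b])
        assert len(clusters) == 1

    def test_identity_threshold_split(self):
        n8 = round(len(BASE) * 0.05)
        a = make_orf(BASE, orf_id="a")
        b = make_orf(_mutate(BASE, n8), orf_id="b")  # ~95% to a
        c = make_orf("MW" * (len(BASE) // 2), orf_id="c")  # unrelated
        clusters = cluster_orfs([a, b, c])
        sizes = sorted(len(cl.members) for cl in clusters)
        assert sizes == [1, 2]

    def test_single_linkage_transitivity(self):
        # a~b and b~c above PI, a~c below: one cluster by transitivity
        n = round(len(BASE) * 0.08)
        a = make_orf(BASE, orf_id="a")
        b_seq = _mutate(BASE, n, alt="W")
        c_seq = _mutate(b_seq, n, alt="H", phase=len(BASE) // (2 * n))
        b = make_orf(b_seq, orf_id="b")
        c = make_orf(c_seq, orf_id="c")
        from orfgraph._align import percent_identity

        assert percent_identity(a.aa_seq, b.aa_seq) > 90
        assert percent_identity(b.aa_seq, c.aa_seq) > 90
        assert percent_identity(a.aa_seq, c.aa_seq) < 90
        clusters = cluster_orfs([a, b, c])
        assert len(clusters) == 1

    def test_order_invariance(self):
        n8 = round(len(BASE) * 0.05)
        orfs = [
            make_orf(BASE, orf_id="a"),
            make_orf(_mutate(BASE, n8), orf_id="b"),
            make_orf("MW" * (len(BASE) // 2), orf_id="c"),
            make_orf(BASE[5:80], orf_id="d"),
        ]
        reference = None
        for perm in permutations(orfs):
            clusters = cluster_orfs(list(perm))
            shape = [sorted(o.orf_id for o in c.members) for c in clusters]
            if reference is None:
                reference = shape
            assert shape == reference

    def test_merging_clusters_never_splits(self):
        n8 = round(len(BASE) * 0.05)
        g1 = [make_orf(BASE, orf_id="a"), make_orf(_mutate(BASE, n8), orf_id="b")]
        g2 = [make_orf("MW" * 100, orf_id="c")]
        merged = cluster_orfs(g1 + g2)
        assert len(merged) <= len(cluster_orfs(g1)) + len(cluster_orfs(g2))


class TestRankTriplet:
    def test_lexicographic_on_second_component(self):
        a = make_orf("M", triplet=(0.9, 10.0, 3000))
        b = make_orf("M", triplet=(0.9, 12.0, 100))
        assert rank_triplet(b) > rank_triplet(a)

    def test_first_component_dominates(self):
        a = make_orf("M", triplet=(1.0, 1.0, 1))
        b = make_orf("M", triplet=(0.5, 99.0, 9999))
        assert rank_triplet(a) > rank_triplet(b)

    def test_equal_triplets_tie_broken_by_id(self, filter_scenario):
        graph, _, paths = filter_scenario
        a = make_orf("M", path=paths["yellow"], triplet=(1.0, 1.0, 1), orf_id="a")
        b = make_orf("M", path=paths["yellow"], triplet=(1.0, 1.0, 1), orf_id="b")
        from orfgraph.clustering import Cluster

        reps = select_representatives(Cluster(members=[b, a]), graph)
        assert reps[0].orf_id == "a"


def _toy_graph_with_long_edges(edge_ids, long_ids):
    edges = {e: ("A" * 1500 if e in long_ids else "A" * 100) for e in edge_ids}
    return AssemblyGraph(edges, 0)


def _orf_on(graph, steps, orf_id, triplet=(1.0, 1.0, 100)):
    return make_orf(
        "M" + orf_id, path=GraphPath([(s, "+") for s in steps], 0, 10),
        orf_id=orf_id, triplet=triplet,
    )


class TestRepresentatives:
    def test_single_long_edge_single_representative(self):
        g = _toy_graph_with_long_edges("XYZ", {"Y"})
        from orfgraph.clustering import Cluster

        members = [
            _orf_on(g, "XY", "a", (1.0, 5.0, 100)),
            _orf_on(g, "YZ", "b", (1.0, 9.0, 100)),
            _orf_on(g, "XYZ"[1:], "c", (0.5, 1.0, 100)),
        ]
        reps = select_representatives(Cluster(members=members), g)
        assert [r.orf_id for r in reps] == ["b"]  # highest triplet covers Y

    def test_disjoint_long_edges_need_two_representatives(self):
        g = _toy_graph_with_long_edges("VWXYZ", {"V", "Z"})
        from orfgraph.clustering import Cluster

        members = [
            _orf_on(g, "VW", "a", (1.0, 9.0, 100)),
            _orf_on(g, "WX", "b", (1.0, 8.0, 100)),
            _orf_on(g, "YZ", "c", (1.0, 7.0, 100)),
        ]
        reps = select_representatives(Cluster(members=members), g)
        assert [r.orf_id for r in reps] == ["a", "c"]

    def test_no_long_edges_one_representative(self):
        g = _toy_graph_with_long_edges("XY", set())
        from orfgraph.clustering import Cluster

        members = [_orf_on(g, "X", "a", (0.2, 1.0, 1)), _orf_on(g, "Y", "b", (0.9, 1.0, 1))]
        reps = select_representatives(Cluster(members=members), g)
        assert [r.orf_id for r in reps] == ["b"]

    def test_cover_matches_bruteforce_oracle_on_5_member_clusters(self, rng):
        """Greedy cover always covers every long edge that any subset can."""
        from orfgraph.clustering import Cluster

        edge_ids = "ABCDEFG"
        for trial in range(30):
            long_ids = {
                e for e in edge_ids if rng.random() < 0.5
            }
            g = _toy_graph_with_long_edges(edge_ids, long_ids)
            members = []
            for m in range(5):
                k = int(rng.integers(1, 4))
                lo = int(rng.integers(0, len(edge_ids) - k))
                steps = edge_ids[lo : lo + k]
                members.append(
                    _orf_on(g, steps, f"m{m}", (float(rng.random()), 1.0, 100))
                )
            cluster = Cluster(members=list(members))
            reps = select_representatives(cluster, g)
            covered = {
                e for r in reps for e, _ in r.path.steps
            } & cluster.long_cluster_edges
            # oracle: best possible coverage over all subsets
            best = set()
            for size in range(1, 6):
                for subset in combinations(members, size):
                    cov = {
                        e for o in subset for e, _ in o.path.steps
                    } & cluster.long_cluster_edges
                    best |= cov
            assert covered == best == cluster.long_cluster_edges

    def test_ascending_scan_order_flag(self):
        g = _toy_graph_with_long_edges("XY", {"X"})
        from orfgraph.clustering import Cluster

        members = [
            _orf_on(g, "X", "a", (0.1, 1.0, 1)),
            _orf_on(g, "XY", "b", (0.9, 1.0, 1)),
        ]
        reps = select_representatives(
            Cluster(members=list(members)), g, scan_order="ascending"
        )
        assert [r.orf_id for r in reps] == ["a"]  # least reliable first
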