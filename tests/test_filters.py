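"""Position likelihood, unique edges, contig compatibility, similarity."""

import pytest

from conftest import make_orf
from orfgraph.filters import (
    SimilarityThresholds,
    UniqueEdgeParams,
    distance_likelihood,
    filter_contradicting,
    is_unique_edge,
    paths_compatible,
    similarity_classify,
    train_position_model,
)
from orfgraph.graph import GraphPath, reverse_path


class TestPositionLikelihood:
    def test_degenerate_histogram(self):
        m = train_position_model([("M", "g1", 0), ("M", "g2", 0), ("M", "g3", 0)])
        assert distance_likelihood(m, "M", 0) == 1.0

    def test_half_in_window(self):
        m = train_position_model([("M", "g1", 0), ("M", "g2", 1000)])
        assert distance_likelihood(m, "M", 0) == 0.5

    def test_all_in_window(self):
        m = train_position_model([("M", "g", 100), ("M", "g", 200), ("M", "g", 300)])
        assert distance_likelihood(m, "M", 200) == 1.0

    def test_unknown_model_no_penalty(self):
        m = train_position_model([("M", "g", 5)])
        assert distance_likelihood(m, "other", 123) == 1.0

    def test_uniform_histogram_closed_form(self):
        # uniform integers on [0, R]: interior likelihood = (2b+1)/(R+1)
        R, b = 3000, 150
        m = train_position_model([("M", "g", d) for d in range(R + 1)])
        for d in (500, 1500, 2500):
            assert distance_likelihood(m, "M", d) == pytest.approx(
                (2 * b + 1) / (R + 1), abs=1 / 3000
            )

    def test_bounds(self):
        m = train_position_model([("M", "g", d) for d in (0, 10, 5000)])
        for d in (0, 100, 6000):
            assert 0.0 <= distance_likelihood(m, "M", d) <= 1.0


class TestUniqueEdges:
    def test_reference_unique_classification(self, filter_scenario):
        graph, _, _ = filter_scenario
        unique = {e for e in graph.edges if is_unique_edge(graph, e)}
        assert unique == {"B1", "D1"}

    def test_short_edge_between_branches_not_unique(self, filter_scenario):
        graph, _, _ = filter_scenario
        assert graph.length("B2") == 200  # below the 300-nt threshold
        assert not is_unique_edge(graph, "B2")

    def test_degree_condition(self, filter_scenario):
        graph, _, _ = filter_scenario
        # A's start has no branching: outdegree proxy 1
        assert not is_unique_edge(graph, "A")
        assert not is_unique_edge(graph, "C") and not is_unique_edge(graph, "E")

    def test_min_length_configurable(self, filter_scenario):
        graph, _, _ = filter_scenario
        assert not is_unique_edge(graph, "B1", UniqueEdgeParams(min_length=500))


class TestCompatibility:
    def test_containment(self, filter_scenario):
        graph, contigs, paths = filter_scenario
        assert paths_compatible(paths["yellow"], contigs["green_contig"], graph)

    def test_dovetail_overlap(self, filter_scenario):
        graph, _, _ = filter_scenario
        p = GraphPath.full(graph, [("A", "+"), ("B1", "+"), ("C", "+")])
        q = GraphPath.full(graph, [("C", "+"), ("D1", "+"), ("E", "+")])
        long_q = GraphPath.full(graph, [("B1", "+"), ("C", "+"), ("D1", "+")])
        assert paths_compatible(p, long_q, graph)  # suffix [B1,C] = prefix
        assert paths_compatible(long_q, q, graph)

    def test_shared_middle_with_divergent_ends(self, filter_scenario):
        graph, contigs, paths = filter_scenario
        assert not paths_compatible(paths["red"], contigs["green_contig"], graph)

    def test_symmetric_self_and_strand_aware(self, filter_scenario):
        graph, contigs, paths = filter_scenario
        green = contigs["green_contig"]
        for p in paths.values():
            assert paths_compatible(p, p, graph)
            assert paths_compatible(p, green, graph) == paths_compatible(
                green, p, graph
            )
            assert paths_compatible(p, green, graph) == paths_compatible(
                reverse_path(graph, p), green, graph
            )


class TestContigFilter:
    def test_contig_filter_scenario(self, filter_scenario):
        graph, contigs, paths = filter_scenario
        orfs = [
            make_orf("A" * 10, path=paths[name], orf_id=name)
            for name in ("red", "blue", "yellow")
        ]
        kept, removed = filter_contradicting(
            orfs, [contigs["green_contig"]], graph
        )
        assert {o.orf_id for o in kept} == {"blue", "yellow"}
        assert list(removed) == [0]  # red, against contig 0

    def test_orf_without_unique_edges_always_kept(self, filter_scenario):
        graph, contigs, _ = filter_scenario
        p = GraphPath.full(graph, [("A", "+"), ("B2", "+"), ("C", "+")])
        kept, removed = filter_contradicting(
            [make_orf("A" * 5, path=p)], [contigs["green_contig"]], graph
        )
        assert len(kept) == 1 and not removed

    def test_subpath_of_contig_never_removed(self, filter_scenario):
        graph, contigs, _ = filter_scenario
        for steps in (["B1", "C"], ["A", "B1"], ["C", "D1", "E"]):
            p = GraphPath.full(graph, [(s, "+") for s in steps])
            kept, removed = filter_contradicting(
                [make_orf("A" * 5, path=p)], [contigs["green_contig"]], graph
            )
            assert len(kept) == 1 and not removed


class TestSimilarity:
    BASE = (
        "MKVLAATGRESLDKVNQLIEDFSGKAPQWVRENAYHLIKEAGLDTPEQVVREAMKQLQ"
        "PDEVKRLGEYSARTMWDKLTPEERAAFDEKAQALIAEYGLSNPDKVNELAGKWGLDTPE"
    )

    def _mutate(self, seq, n):
        # substitutions spread evenly so local alignment cannot trim them
        out = list(seq)
        for i in range(n):
            pos = (i * len(seq)) // n
            out[pos] = "W" if out[pos] != "W" else "Y"
        return "".join(out)

    def test_identical_is_known(self):
        orf = make_orf(self.BASE)
        verdict, hit, pid = similarity_classify(orf, {"db1": self.BASE})
        assert verdict == "reliable-known" and pid == 100.0

    def test_95_percent_is_novel(self):
        n = round(len(self.BASE) * 0.05)
        orf = make_orf(self._mutate(self.BASE, n))
        verdict, _, pid = similarity_classify(orf, {"db1": self.BASE})
        assert verdict == "reliable-novel"
        assert 90 < pid < 100

    def test_dissimilar_is_candidate(self):
        orf = make_orf("MW" * 40)
        verdict, _, pid = similarity_classify(orf, {"db1": self.BASE})
        assert verdict == "candidate" and pid < 80

    def test_between_retain_and_novel_is_reliable(self):
        n = round(len(self.BASE) * 0.15)
        orf = make_orf(self._mutate(self.BASE, n))
        verdict, _, pid = similarity_classify(orf, {"db1": self.BASE})
        assert verdict == "reliable"
        assert 80 <= pid <= 90

    def test_empty_db_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            similarity_classify(make_orf("MKV"), {})

    def test_threshold_ordering_enforced(self):
        with pytest.raises(ValueError):
            SimilarityThresholds(retain_identity=95, reliable_identity=80)
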