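"""CDS building: reachability, bounded enumeration, candidate assembly."""

import numpy as np
import pytest

from orfgraph._align import translate
from orfgraph.anchors import find_anchors_bruteforce
from orfgraph.cds import (
    BuilderLimits,
    build_candidates,
    enumerate_paths,
    reachable_edges,
    within_length_limit,
)
from orfgraph.codons import find_start_codons, find_stop_codons
from orfgraph.fixtures import FixtureSpec, generate_fixture
from orfgraph.graph import AssemblyGraph, pos_at, spell, spelled_length
from oracles import (
    base_chain_to_steps,
    brute_enumerate_paths,
    random_consistent_graph,
)


def _diamond(long_branch=14):
    ov = 3
    a, c = "ACGTTGCA", "TTACGGAT"
    b1 = a[-ov:] + "GG" + c[:ov]
    b2 = a[-ov:] + "G" * long_branch + c[:ov]
    return AssemblyGraph(
        {"A": a, "B1": b1, "B2": b2, "C": c}, ov,
        links=[
            (("A", "+"), ("B1", "+")), (("A", "+"), ("B2", "+")),
            (("B1", "+"), ("C", "+")), (("B2", "+"), ("C", "+")),
        ],
    )


class TestReachableEdges:
    def test_same_edge(self):
        g = _diamond()
        assert reachable_edges(g, ("A", "+", 1), ("A", "+", 6), 100) == {("A", "+")}

    def test_diamond_both_branches(self):
        g = _diamond()
        got = reachable_edges(g, ("A", "+", 0), ("C", "+", 8), 100)
        assert got == {("A", "+"), ("B1", "+"), ("B2", "+"), ("C", "+")}

    def test_diamond_budget_excludes_long_branch(self):
        # path via B1 spells 18 nt; via B2, 30 nt
        g = _diamond()
        got = reachable_edges(g, ("A", "+", 0), ("C", "+", 8), 18)
        assert got == {("A", "+"), ("B1", "+"), ("C", "+")}

    def test_matches_bruteforce_on_random_graphs(self):
        rng = np.random.default_rng(13)
        checked = 0
        while checked < 60:
            g = random_consistent_graph(
                rng, n_junctions=int(rng.integers(3, 6)),
                n_edges=int(rng.integers(4, 9)),
            )
            edges = sorted(g.edges)
            ve = edges[int(rng.integers(0, len(edges)))]
            we = edges[int(rng.integers(0, len(edges)))]
            v = (ve, "+", int(rng.integers(0, g.length(ve))))
            w = (we, "+", int(rng.integers(1, g.length(we) + 1)))
            ml = int(rng.integers(1, 60))
            checked += 1
            oracle = set()
            for chain in brute_enumerate_paths(g, v, w, ml):
                oracle.update(base_chain_to_steps(g, chain))
            assert reachable_edges(g, v, w, ml) == oracle


class TestEnumeratePaths:
    def test_linear_chain_single_path(self, two_edge_graph):
        paths, trunc = enumerate_paths(
            two_edge_graph, ("1", "+", 0), ("2", "+", 5), BuilderLimits()
        )
        assert not trunc and len(paths) == 1
        assert spell(two_edge_graph, paths[0]) == "ACGTACC"

    @pytest.mark.parametrize("n,expected", [(3, 8), (9, 512)])
    def test_serial_bubbles_combinatorial_count(self, n, expected):
        spec = FixtureSpec(n_bubbles=n, gene_aa_len=500 if n >= 9 else 300, seed=5)
        g, _, truth = generate_fixture(spec)
        t = truth.genes[0]
        L = spelled_length(g, t.path)
        v = pos_at(g, t.path, 0)
        e, o, off = pos_at(g, t.path, L - 1)
        paths, trunc = enumerate_paths(g, v, (e, o, off + 1), BuilderLimits())
        assert not trunc and len(paths) == expected

    def test_thousand_path_cap_with_flag(self):
        spec = FixtureSpec(n_bubbles=10, gene_aa_len=500, seed=5)
        g, _, truth = generate_fixture(spec)
        t = truth.genes[0]
        L = spelled_length(g, t.path)
        v = pos_at(g, t.path, 0)
        e, o, off = pos_at(g, t.path, L - 1)
        paths, trunc = enumerate_paths(g, v, (e, o, off + 1), BuilderLimits())
        assert trunc and len(paths) == 1000

    def test_matches_bruteforce_on_random_graphs(self):
        rng = np.random.default_rng(7)
        checked = 0
        while checked < 60:
            g = random_consistent_graph(
                rng, n_junctions=int(rng.integers(3, 6)),
                n_edges=int(rng.integers(4, 9)),
            )
            edges = sorted(g.edges)
            ve = edges[int(rng.integers(0, len(edges)))]
            we = edges[int(rng.integers(0, len(edges)))]
            v = (ve, "+", int(rng.integers(0, g.length(ve))))
            w = (we, "+", int(rng.integers(1, g.length(we) + 1)))
            ml = int(rng.integers(1, 60))
            checked += 1
            impl, _ = enumerate_paths(
                g, v, w, BuilderLimits(max_paths_per_pair=100000), max_len=ml
            )
            impl_set = sorted((p.steps, spelled_length(g, p)) for p in impl)
            oracle = sorted(
                {
                    (base_chain_to_steps(g, c), len(c))
                    for c in brute_enumerate_paths(g, v, w, ml)
                }
            )
            assert impl_set == oracle


def _pipeline_sites(graph, gene, protein=None, limits=BuilderLimits()):
    anchors = find_anchors_bruteforce(graph, {"p": protein or gene.aa_seq})
    anchor = next(
        a for a in anchors if spell(graph, a.path) == gene.nt_seq[:-3]
    )
    alen = spelled_length(graph, anchor.path)
    md = max(0, limits.max_restorable_length - alen)
    return (
        anchor,
        find_start_codons(graph, anchor, md),
        find_stop_codons(graph, anchor, md),
    )


class TestBuildCandidates:
    def test_unique_start_stop_yields_embedded_protein(self, bubble_fixture):
        graph, _, truth = bubble_fixture
        gene = truth.genes[0]
        anchor, starts, stops = _pipeline_sites(graph, gene)
        orfs = build_candidates(anchor, starts, stops, graph)
        assert any(o.aa_seq == gene.aa_seq for o in orfs)
        true_orf = next(o for o in orfs if o.aa_seq == gene.aa_seq)
        assert true_orf.nt_seq == gene.nt_seq

    def test_roundtrip_spell_and_translate(self, bubble_fixture):
        graph, _, truth = bubble_fixture
        gene = truth.genes[0]
        anchor, starts, stops = _pipeline_sites(graph, gene)
        for orf in build_candidates(anchor, starts, stops, graph):
            assert spell(graph, orf.path) == orf.nt_seq
            assert translate(orf.nt_seq[:-3]) == orf.aa_seq
            assert len(orf.nt_seq) % 3 == 0
            assert orf.nt_seq[:3] in {"ATG", "GTG", "TTG"}
            assert orf.nt_seq[-3:] in {"TAA", "TAG", "TGA"}

    def test_length_boundary(self):
        limits = BuilderLimits()
        assert within_length_limit(3000, limits)
        assert not within_length_limit(3001, limits)

    def test_overlong_concatenate_discarded_end_to_end(self):
        # 3000-nt CDS is kept; a 3003-nt CDS exceeds the restorable length
        for aa_len, expect in [(999, True), (1000, False)]:
            spec = FixtureSpec(gene_aa_len=aa_len, seed=9, flank=200)
            g, _, truth = generate_fixture(spec)
            gene = truth.genes[0]
            assert len(gene.nt_seq) == 3 * aa_len + 3
            anchor, starts, stops = _pipeline_sites(g, gene)
            orfs = build_candidates(anchor, starts, stops, g)
            assert any(o.aa_seq == gene.aa_seq for o in orfs) is expect

    def test_duplicate_amino_acid_sequences_collapse(self, bubble_fixture):
        graph, _, truth = bubble_fixture
        gene = truth.genes[0]
        anchor, starts, stops = _pipeline_sites(graph, gene)
        orfs = build_candidates(anchor, starts, stops, graph)
        assert len({o.aa_seq for o in orfs}) == len(orfs)

    def test_deterministic_output(self, bubble_fixture):
        graph, _, truth = bubble_fixture
        gene = truth.genes[0]
        anchor, starts, stops = _pipeline_sites(graph, gene)
        a = build_candidates(anchor, starts, stops, graph)
        b = build_candidates(anchor, list(reversed(starts)), list(reversed(stops)), graph)
        assert [(o.nt_seq, o.path.key()) for o in a] == [
            (o.nt_seq, o.path.key()) for o in b
        ]
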