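import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from orfgraph.anchors import AnchorPath
from orfgraph.cds import CandidateORF
from orfgraph.fixtures import FixtureSpec, generate_contig_filter_graph, generate_fixture
from orfgraph.graph import AssemblyGraph, GraphPath


@pytest.fixture
def two_edge_graph():
    """S '1 ACGTA', S '2 GTACC', overlap 3 -- the minimal linked pair."""
    return AssemblyGraph(
        {"1": "ACGTA", "2": "GTACC"}, 3, links=[(("1", "+"), ("2", "+"))]
    )


@pytest.fixture
def filter_scenario():
    """(graph, contigs, labeled paths) for the unique-edge filter scenario."""
    return generate_contig_filter_graph()


@pytest.fixture
def bubble_fixture():
    """Two-bubble single-gene fixture with unitig contigs and truth."""
    return generate_fixture(FixtureSpec(n_bubbles=2, seed=3))


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def make_orf(aa_seq, path=None, triplet=(1.0, 0.0, 0), orf_id="", nt_seq=""):
    """CandidateORF stub for clustering / filter tests."""
    if path is None:
        path = GraphPath([("X", "+")], 0, 1)
    anchor = AnchorPath(
        path=path, query_id="q", query_span=(0, max(len(aa_seq), 1)),
        query_len=max(len(aa_seq), 1),
    )
    return CandidateORF(
        path=path,
        nt_seq=nt_seq,
        aa_seq=aa_seq,
        source_anchor=anchor,
        start_site=None,
        stop_site=None,
        triplet=triplet,
        orf_id=orf_id,
    )
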