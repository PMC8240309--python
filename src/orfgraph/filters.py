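"""Ranking and filtering of candidate ORFs.

Three independent ingredients:

* a position-likelihood model -- the empirical distribution of distances
  from gene starts to profile-model hit starts, smoothed over a +-binSize
  window, used as the first component of the ranking triplet;
* contig-compatibility filtering -- a candidate that shares a *unique*
  edge with an assembler contig path but is neither contained in it nor
  dovetails with it contradicts the contig and is removed;
* similarity classification against the user's database of known
  proteins, separating reliable (>= 80% identity by default) from
  candidate predictions and marking near-identical hits as known/novel.
"""

from __future__ import annotations

import bisect
import csv
from dataclasses import dataclass, field

from . import _align
from .cds import CandidateORF
from .graph import (
    AssemblyGraph,
    GraphPath,
    is_step_subpath,
    reverse_path,
    steps_dovetail,
)

__all__ = [
    "PositionLikelihoodModel",
    "UniqueEdgeParams",
    "SimilarityThresholds",
    "train_position_model",
    "distance_likelihood",
    "is_unique_edge",
    "paths_compatible",
    "filter_contradicting",
    "similarity_classify",
    "path_coverage",
]


@dataclass
class PositionLikelihoodModel:
    """Per-model multisets of observed gene-start-to-hit-start distances (nt)."""

    distances: dict[str, list[int]] = field(default_factory=dict)
    bin_size: int = 150
    min_likelihood: float = 0.05


def train_position_model(
    model_hits: list[tuple[str, str, int]], bin_size: int = 150
) -> PositionLikelihoodModel:
    """``model_hits``: (model-id, gene-id, start-distance nt) records."""
    model = PositionLikelihoodModel(bin_size=bin_size)
    for model_id, _gene_id, dist in model_hits:
        if dist < 0:
            raise ValueError(f"negative distance {dist} for model {model_id}")
        model.distances.setdefault(model_id, []).append(int(dist))
    for lst in model.distances.values():
        lst.sort()
    return model


def load_model_hits(path: str) -> list[tuple[str, str, int]]:
    """Training table TSV: model_id, gene_id, distance_nt."""
    hits = []
    with open(path) as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0].startswith("#"):
                continue
            hits.append((row[0], row[1], int(row[2])))
    return hits


def distance_likelihood(model: PositionLikelihoodModel, model_id: str, d: int) -> float:
    """Fraction of training distances within [d - binSize, d + binSize];
    models never seen in training carry no evidence and return 1.0."""
    if d < 0:
        raise ValueError("distance must be >= 0")
    dists = model.distances.get(model_id)
    if not dists:
        return 1.0
    lo = bisect.bisect_left(dists, d - model.bin_size)
    hi = bisect.bisect_right(dists, d + model.bin_size)
    return (hi - lo) / len(dists)


@dataclass(frozen=True)
class UniqueEdgeParams:
    min_length: int = 300
    # "printed": length > minLength AND outdegree(start node) > 1 AND
    #            indegree(end node) > 1, exactly as stated;
    # "inverted": the degree conditions replaced by == 1.
    degree_convention: str = "printed"

    def __post_init__(self):
        if self.min_length <= 0:
            raise ValueError("min_length must be > 0")
        if self.degree_convention not in ("printed", "inverted"):
            raise ValueError(self.degree_convention)


def is_unique_edge(
    graph: AssemblyGraph, edge_id: str, params: UniqueEdgeParams = UniqueEdgeParams()
) -> bool:
    """Heuristic for edges traversed once by the genome path."""
    if graph.length(edge_id) <= params.min_length:
        return False
    oe = (edge_id, "+")
    outdeg = len(graph.out_siblings(oe))
    indeg = len(graph.in_siblings(oe))
    if params.degree_convention == "printed":
        return outdeg > 1 and indeg > 1
    return outdeg == 1 and indeg == 1


def paths_compatible(p1: GraphPath, p2: GraphPath, graph: AssemblyGraph) -> bool:
    """True iff one path is contained in the other or a suffix of one
    coincides with a prefix of the other (dovetail), on either strand."""
    a = p1.steps
    for q in (p2, reverse_path(graph, p2)):
        b = q.steps
        if is_step_subpath(a, b) or is_step_subpath(b, a):
            return True
        if steps_dovetail(a, b) or steps_dovetail(b, a):
            return True
    return False


def filter_contradicting(
    orfs: list[CandidateORF],
    contigs: list[GraphPath],
    graph: AssemblyGraph,
    params: UniqueEdgeParams = UniqueEdgeParams(),
) -> tuple[list[CandidateORF], dict[int, int]]:
    """Remove ORFs sharing a unique edge with a contig they are not
    compatible with.  Returns (survivors, {orf index: offending contig
    index}) so reports can name the contradicting contig."""
    unique_cache: dict[str, bool] = {}

    def uniq(eid: str) -> bool:
        if eid not in unique_cache:
            unique_cache[eid] = is_unique_edge(graph, eid, params)
        return unique_cache[eid]

    kept: list[CandidateORF] = []
    removed: dict[int, int] = {}
    for i, orf in enumerate(orfs):
        orf_edges = {e for e, _ in orf.path.steps}
        verdict_contig = None
        for j, contig in enumerate(contigs):
            shared = orf_edges & {e for e, _ in contig.steps}
            if not any(uniq(e) for e in shared):
                continue
            if not paths_compatible(orf.path, contig, graph):
                verdict_contig = j
                break
        if verdict_contig is None:
            kept.append(orf)
        else:
            removed[i] = verdict_contig
    return kept, removed


@dataclass(frozen=True)
class SimilarityThresholds:
    retain_identity: float = 80.0
    reliable_identity: float = 80.0
    novel_low: float = 90.0
    novel_high: float = 100.0  # exclusive

    def __post_init__(self):
        ok = (
            0 < self.retain_identity <= self.reliable_identity
            <= self.novel_low < self.novel_high <= 100.0
        )
        if not ok:
            raise ValueError("thresholds must satisfy 0 < retain <= reliable <= "
                             "novel_low < novel_high <= 100")


def similarity_classify(
    orf: CandidateORF,
    db: dict[str, str],
    thresholds: SimilarityThresholds = SimilarityThresholds(),
) -> tuple[str, str, float]:
    """Best amino-acid identity of the ORF's protein against the database;
    returns (verdict, best-hit id, identity %).  Identity counts matched
    residues over the shorter sequence's length, so a short spurious
    alignment cannot masquerade as a near-identical hit.

    Verdicts: ``candidate`` below the reliable threshold, ``reliable``
    at/above it, refined to ``reliable-novel`` (identity in
    (novel_low, 100)) and ``reliable-known`` (exact match).
    """
    if not db:
        raise ValueError("empty protein database")
    best_id, best_pid = "", 0.0
    for qid, qseq in sorted(db.items()):
        pid = _align.identity_to_shorter(qseq, orf.aa_seq)
        if pid > best_pid:
            best_id, best_pid = qid, pid
    if best_pid < thresholds.reliable_identity:
        return "candidate", best_id, best_pid
    if best_pid >= 100.0:
        return "reliable-known", best_id, best_pid
    if best_pid > thresholds.novel_low:
        return "reliable-novel", best_id, best_pid
    return "reliable", best_id, best_pid


def path_coverage(graph: AssemblyGraph, path: GraphPath) -> float:
    """Length-weighted mean per-edge read coverage along a path (0.0 when
    the graph carries no coverage tags)."""
    if not graph.coverage:
        return 0.0
    num = den = 0.0
    for e, _ in path.steps:
        length = graph.length(e)
        num += graph.coverage.get(e, 0.0) * length
        den += length
    return num / den if den else 0.0
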