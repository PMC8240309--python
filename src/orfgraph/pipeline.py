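"""End-to-end pipeline: anchors -> codon search -> CDS building -> ranking
-> contig filtering -> similarity classification -> clustering ->
representative selection, with standard file outputs.

Outputs written to the run directory:

* ``representatives.faa`` / ``representatives.fna`` -- representative
  proteins / coding sequences (main output; known genes and ORFs found in
  a single contig are excluded unless the corresponding flags are set);
* ``clusters.tsv`` -- cluster membership, long cluster edges, and
  representative flags;
* ``cds_report.tsv`` -- one row per candidate ORF with its graph path,
  codon flags and ranking triplet;
* ``filter_report.tsv`` -- similarity verdicts and contig contradictions;
* ``run_log.json`` -- per-stage counts.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import Optional

from Bio import SeqIO

from . import anchors as anchors_mod
from . import cds as cds_mod
from . import clustering as cluster_mod
from . import codons as codons_mod
from . import filters as filters_mod
from .anchors import AnchorThresholds
from .cds import BuilderLimits, CandidateORF
from .clustering import ClusterParams
from .filters import (
    PositionLikelihoodModel,
    SimilarityThresholds,
    UniqueEdgeParams,
    path_coverage,
)
from .graph import (
    AssemblyGraph,
    GraphPath,
    flip,
    is_step_subpath,
    read_contig_paths,
    read_gfa,
    read_gfa_paths,
    spelled_length,
)

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "count_single_contig"]


@dataclass
class PipelineConfig:
    gfa: str = ""
    proteins: str = ""
    contigs: Optional[str] = None
    contig_paths: Optional[str] = None
    anchors_tsv: Optional[str] = None
    train_hits: Optional[str] = None
    out_dir: str = "orfgraph_out"
    anchor_thresholds: AnchorThresholds = field(default_factory=AnchorThresholds)
    limits: BuilderLimits = field(default_factory=BuilderLimits)
    unique_params: UniqueEdgeParams = field(default_factory=UniqueEdgeParams)
    similarity: SimilarityThresholds = field(default_factory=SimilarityThresholds)
    cluster_params: ClusterParams = field(default_factory=ClusterParams)
    start_codons: frozenset = codons_mod.DEFAULT_START_CODONS
    report_single_contig_hits: bool = False
    report_known: bool = False
    scan_order: str = "descending"
    write_outputs: bool = True


@dataclass
class PipelineResult:
    orfs: list[CandidateORF]
    clusters: list
    representatives: list[CandidateORF]
    main_representatives: list[CandidateORF]
    counts: dict
    removed_by_contig: dict


def count_single_contig(orf: CandidateORF, contigs: list[GraphPath]) -> bool:
    """True iff the ORF's path is contained in some contig path (either
    strand); vacuously false without contigs."""
    steps = orf.path.steps
    for contig in contigs:
        fwd = contig.steps
        rc = tuple(flip(s) for s in reversed(fwd))
        if is_step_subpath(steps, fwd) or is_step_subpath(steps, rc):
            return True
    return False


def _load_fasta(path: str) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}


def _assign_ids(orfs: list[CandidateORF]) -> None:
    ordered = sorted(orfs, key=lambda o: (o.source_anchor.query_id, o.path.key(), o.aa_seq))
    for i, orf in enumerate(ordered, 1):
        orf.orf_id = f"orf{i:04d}"


def run_pipeline(
    config: PipelineConfig,
    graph: Optional[AssemblyGraph] = None,
    proteins: Optional[dict[str, str]] = None,
    contigs: Optional[dict[str, GraphPath]] = None,
    position_model: Optional[PositionLikelihoodModel] = None,
) -> PipelineResult:
    """Run all stages.  Inputs may be passed in memory (tests) or read
    from the files named in ``config``."""
    counts: dict[str, int] = {}
    if graph is None:
        graph = read_gfa(config.gfa)
    if proteins is None:
        proteins = _load_fasta(config.proteins)
    if contigs is None:
        contigs = {}
        if config.contig_paths:
            if config.contig_paths.endswith(".gfa"):
                contigs = read_gfa_paths(config.contig_paths, graph)
            else:
                contigs = read_contig_paths(config.contig_paths, graph)
    contig_list = [contigs[k] for k in sorted(contigs)]

    if position_model is None:
        if config.train_hits:
            position_model = filters_mod.train_position_model(
                filters_mod.load_model_hits(config.train_hits)
            )
        else:
            position_model = PositionLikelihoodModel()

    # 1. anchors
    if config.anchors_tsv:
        anchor_list = anchors_mod.load_external_anchors(
            config.anchors_tsv, graph, config.anchor_thresholds
        )
    else:
        anchor_list = anchors_mod.find_anchors_bruteforce(
            graph, proteins, config.anchor_thresholds
        )
    counts["anchors"] = len(anchor_list)
    anchor_list = anchors_mod.filter_subpath_anchors(anchor_list, graph)
    counts["anchors_after_subpath_filter"] = len(anchor_list)
    if not anchor_list:
        result = PipelineResult([], [], [], [], counts, {})
        if config.write_outputs:
            _write_outputs(config, graph, result, contigs)
        return result

    # 2+3. codon search and CDS building
    all_orfs: list[CandidateORF] = []
    for anchor in anchor_list:
        alen = spelled_length(graph, anchor.path)
        max_dist = max(0, config.limits.max_restorable_length - alen)
        starts = codons_mod.find_start_codons(
            graph, anchor, max_dist, config.start_codons
        )
        stops = codons_mod.find_stop_codons(graph, anchor, max_dist)
        all_orfs.extend(
            cds_mod.build_candidates(
                anchor, starts, stops, graph, config.limits, config.start_codons
            )
        )
    # global dedup on protein sequence
    by_aa: dict[str, CandidateORF] = {}
    for orf in all_orfs:
        if orf.aa_seq not in by_aa:
            by_aa[orf.aa_seq] = orf
    orfs = list(by_aa.values())
    counts["candidate_orfs"] = len(orfs)

    # 4. ranking triplets
    for orf in orfs:
        anchor = orf.source_anchor
        d = _anchor_offset(graph, orf)
        if anchor.kind == "model":
            lk = filters_mod.distance_likelihood(position_model, anchor.query_id, d)
        else:
            lk = 1.0
        orf.triplet = (lk, path_coverage(graph, orf.path), len(orf.nt_seq))
    _assign_ids(orfs)

    # 5. contig-compatibility filter
    kept, removed = filters_mod.filter_contradicting(
        orfs, contig_list, graph, config.unique_params
    )
    removed_by_contig = {
        orfs[i].orf_id: sorted(contigs)[j] for i, j in removed.items()
    }
    counts["after_contig_filter"] = len(kept)

    # 6. similarity classification; below retain -> discarded
    survivors: list[CandidateORF] = []
    for orf in kept:
        verdict, hit, pid = filters_mod.similarity_classify(
            orf, proteins, config.similarity
        )
        orf.best_hit, orf.best_identity = hit, pid
        if pid < config.similarity.retain_identity:
            orf.verdict = "discarded"
            continue
        orf.verdict = verdict
        survivors.append(orf)
    counts["after_similarity_filter"] = len(survivors)

    # 7. clustering and representatives
    clusters = cluster_mod.cluster_orfs(survivors, config.cluster_params, graph)
    counts["clusters"] = len(clusters)
    representatives: list[CandidateORF] = []
    for c in clusters:
        representatives.extend(
            cluster_mod.select_representatives(
                c, graph, config.cluster_params, config.scan_order
            )
        )
    counts["representatives"] = len(representatives)

    # 8. main-output exclusions
    main = []
    for orf in representatives:
        if not config.report_known and orf.verdict == "reliable-known":
            continue
        if not config.report_single_contig_hits and count_single_contig(orf, contig_list):
            continue
        main.append(orf)
    counts["main_representatives"] = len(main)

    result = PipelineResult(orfs, clusters, representatives, main, counts, removed_by_contig)
    if config.write_outputs:
        _write_outputs(config, graph, result, contigs)
    return result


def _anchor_offset(graph: AssemblyGraph, orf: CandidateORF) -> int:
    """nt distance from the ORF start codon to the anchor-path start."""
    from .graph import spell

    anchor_seq = spell(graph, orf.source_anchor.path)
    idx = orf.nt_seq.find(anchor_seq)
    return idx if idx >= 0 else 0


def _write_outputs(config, graph, result: PipelineResult, contigs) -> None:
    os.makedirs(config.out_dir, exist_ok=True)
    od = config.out_dir

    def fasta(path, records, seq_of):
        with open(path, "w") as fh:
            for orf in records:
                fh.write(f">{orf.orf_id} anchor={orf.source_anchor.query_id} "
                         f"verdict={orf.verdict}\n{seq_of(orf)}\n")

    fasta(os.path.join(od, "representatives.faa"), result.main_representatives,
          lambda o: o.aa_seq)
    fasta(os.path.join(od, "representatives.fna"), result.main_representatives,
          lambda o: o.nt_seq)
    fasta(os.path.join(od, "representatives_full.faa"), result.representatives,
          lambda o: o.aa_seq)

    with open(os.path.join(od, "clusters.tsv"), "w") as fh:
        fh.write("cluster_id\torf_id\tis_representative\tlong_cluster_edges\n")
        for ci, c in enumerate(result.clusters, 1):
            reps = {o.orf_id for o in c.representatives}
            for o in c.members:
                fh.write(
                    f"cluster{ci:03d}\t{o.orf_id}\t{int(o.orf_id in reps)}\t"
                    + ",".join(sorted(c.long_cluster_edges))
                    + "\n"
                )

    with open(os.path.join(od, "cds_report.tsv"), "w") as fh:
        fh.write(
            "orf_id\tanchor_query\tpath\tnt_len\tflags\t"
            "likelihood\tcoverage\tpath_len\n"
        )
        for o in sorted(result.orfs, key=lambda x: x.orf_id):
            path = ",".join(f"{e}{s}" for e, s in o.path.steps)
            fh.write(
                f"{o.orf_id}\t{o.source_anchor.query_id}\t{path}\t{len(o.nt_seq)}\t"
                f"{','.join(sorted(o.flags))}\t"
                f"{o.triplet[0]:.4f}\t{o.triplet[1]:.2f}\t{o.triplet[2]}\n"
            )

    with open(os.path.join(od, "filter_report.tsv"), "w") as fh:
        fh.write("orf_id\tverdict\tbest_hit\tidentity\tcontradicting_contig\n")
        for o in sorted(result.orfs, key=lambda x: x.orf_id):
            contra = result.removed_by_contig.get(o.orf_id, "")
            verdict = o.verdict or ("contig-contradiction" if contra else "")
            fh.write(f"{o.orf_id}\t{verdict}\t{o.best_hit}\t{o.best_identity:.1f}\t{contra}\n")

    with open(os.path.join(od, "run_log.json"), "w") as fh:
        json.dump({"counts": result.counts}, fh, indent=2, sort_keys=True)
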