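"""Shared pairwise protein-alignment helpers (BLOSUM62 via Bio.Align)."""

from __future__ import annotations

from functools import lru_cache

from Bio import Align
from Bio.Align import substitution_matrices
from Bio.Data.CodonTable import TranslationError
from Bio.Seq import Seq

BACTERIAL_TABLE = 11


@lru_cache(maxsize=4)
def _aligner(mode: str) -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.substitution_matrix = substitution_matrices.load("BLOSUM62")
    a.open_gap_score = -11.0
    a.extend_gap_score = -1.0
    a.mode = mode
    if mode == "global":
        # free terminal gaps: identity is measured over the aligned region
        a.end_gap_score = 0.0
    return a


def translate(nt: str, table: int = BACTERIAL_TABLE) -> str:
    """Translate a frame-trimmed nucleotide string (no stop handling)."""
    try:
        return str(Seq(nt).translate(table=table))
    except TranslationError as exc:  # pragma: no cover - guarded by callers
        raise ValueError(str(exc)) from exc


def best_local_alignment(query: str, target: str):
    """Optimal local alignment of ``query`` vs ``target`` or None if empty."""
    if not query or not target:
        return None
    alns = _aligner("local").align(target, query)
    try:
        return alns[0]
    except IndexError:
        return None


def alignment_stats(aln) -> tuple[float, tuple[int, int], tuple[int, int]]:
    """(percent identity over aligned columns excl. terminal gaps,
    target span, query span) for a Bio.Align.Alignment."""
    c = aln.counts()
    cols = c.identities + c.mismatches + c.internal_gaps
    pid = 100.0 * c.identities / cols if cols else 0.0
    tblocks, qblocks = aln.aligned
    if len(tblocks) == 0 or len(qblocks) == 0:  # empty local alignment
        return 0.0, (0, 0), (0, 0)
    tspan = (int(tblocks[0][0]), int(tblocks[-1][1]))
    qspan = (int(qblocks[0][0]), int(qblocks[-1][1]))
    return pid, tspan, qspan


def percent_identity(a: str, b: str, mode: str = "global") -> float:
    """Percent identity between two protein sequences.

    ``global`` uses end-gap-free global alignment; terminal gaps are
    excluded from the denominator.  ``local`` uses Smith-Waterman.
    Note this is identity over the *aligned region*; see
    :func:`identity_to_shorter` for a metric robust to degenerate
    few-column alignments.
    """
    if not a or not b:
        return 0.0
    alns = _aligner(mode).align(a, b)
    try:
        aln = alns[0]
    except IndexError:
        return 0.0
    pid, _, _ = alignment_stats(aln)
    return pid


def identity_to_shorter(a: str, b: str) -> float:
    """Percent of the shorter sequence's residues matched identically in an
    end-gap-free global alignment.

    Unlike aligned-region identity, a degenerate alignment covering a
    handful of columns cannot score high: an exact substring or full match
    gives 100, unrelated sequences stay near 0.
    """
    if not a or not b:
        return 0.0
    alns = _aligner("global").align(a, b)
    try:
        aln = alns[0]
    except IndexError:
        return 0.0
    c = aln.counts()
    return 100.0 * c.identities / min(len(a), len(b))
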