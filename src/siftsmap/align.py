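"""Local pairwise alignment primitives.

A thin layer over Biopython's :class:`Bio.Align.PairwiseAligner` that
returns explicit gapped strings with 1-based inclusive coordinates, plus a
declumped multi-alignment search that reports several mutually
non-overlapping (on the query) local alignments in descending score order.

Gap convention: a gap of length L costs ``gap_open + L * gap_extend``
(BLAST-style affine penalties).
"""
from __future__ import annotations

from dataclasses import dataclass, field

from Bio import Align
from Bio.Align import substitution_matrices

from .errors import InputError
from .residues import VALID_LETTERS

__all__ = ["AlignerParams", "LocalAlignment", "best_local_alignment", "local_alignments"]


@dataclass
class AlignerParams:
    """Alignment parameters; defaults suit the chain-vs-reference step."""

    matrix_name: str = "BLOSUM62"
    gap_open: float = 10.0
    gap_extend: float = 1.0
    max_alignments: int = 10
    min_score: float = 40.0


@dataclass
class LocalAlignment:
    """One gapped local alignment with 1-based inclusive coordinates."""

    query_aligned: str
    target_aligned: str
    query_start: int
    query_end: int
    target_start: int
    target_end: int
    score: float
    identity: float = field(default=0.0)

    def __post_init__(self):
        if len(self.query_aligned) != len(self.target_aligned):
            raise InputError("gapped alignment strings differ in length")

    @property
    def columns(self) -> list[tuple[str, str]]:
        return list(zip(self.query_aligned, self.target_aligned))

    def recompute_identity(self) -> None:
        cols = self.columns
        if not cols:
            self.identity = 0.0
            return
        identical = sum(1 for q, t in cols if q != "-" and q == t)
        self.identity = identical / len(cols)


def _validate_sequence(seq: str, what: str) -> None:
    if not seq:
        raise InputError(f"{what} sequence is empty")
    bad = set(seq.upper()) - VALID_LETTERS
    if bad:
        raise InputError(f"{what} sequence has non-amino-acid letters: {sorted(bad)}")


def make_aligner(params: AlignerParams) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load(params.matrix_name)
    aligner.mode = "local"
    # first gap residue pays open + extend, later residues pay extend
    aligner.open_gap_score = -(params.gap_open + params.gap_extend)
    aligner.extend_gap_score = -params.gap_extend
    return aligner


def _from_biopython(alignment, query: str, target: str, q_offset: int) -> LocalAlignment:
    coords = alignment.coordinates
    qa_parts: list[str] = []
    ta_parts: list[str] = []
    for i in range(coords.shape[1] - 1):
        q0, q1 = int(coords[0, i]), int(coords[0, i + 1])
        t0, t1 = int(coords[1, i]), int(coords[1, i + 1])
        dq, dt = q1 - q0, t1 - t0
        if dq and dt:
            qa_parts.append(query[q0:q1])
            ta_parts.append(target[t0:t1])
        elif dq:
            qa_parts.append(query[q0:q1])
            ta_parts.append("-" * dq)
        elif dt:
            qa_parts.append("-" * dt)
            ta_parts.append(target[t0:t1])
    result = LocalAlignment(
        query_aligned="".join(qa_parts),
        target_aligned="".join(ta_parts),
        query_start=q_offset + int(coords[0, 0]) + 1,
        query_end=q_offset + int(coords[0, -1]),
        target_start=int(coords[1, 0]) + 1,
        target_end=int(coords[1, -1]),
        score=float(alignment.score),
    )
    result.recompute_identity()
    return result


def best_local_alignment(
    query: str, target: str, params: AlignerParams | None = None
) -> LocalAlignment | None:
    """Single best local alignment, or None when no positive-scoring pair exists."""
    params = params or AlignerParams()
    _validate_sequence(query, "query")
    _validate_sequence(target, "target")
    aligner = make_aligner(params)
    alignments = aligner.align(query.upper(), target.upper())
    if alignments.score <= 0:
        return None
    return _from_biopython(alignments[0], query.upper(), target.upper(), 0)


def local_alignments(
    query: str, target: str, params: AlignerParams | None = None
) -> list[LocalAlignment]:
    """Multiple non-overlapping (on the query) local alignments.

    Declumping by recursive query splitting: the best alignment is taken,
    then the query stretches left and right of it are re-aligned against
    the full target.  Results are sorted by descending score (ties by
    query_start) and truncated at ``params.max_alignments``; alignments
    scoring below ``params.min_score`` are discarded.
    """
    params = params or AlignerParams()
    _validate_sequence(query, "query")
    _validate_sequence(target, "target")
    query = query.upper()
    target = target.upper()
    aligner = make_aligner(params)
    results: list[LocalAlignment] = []

    def recurse(lo: int, hi: int) -> None:
        if hi - lo < 1:
            return
        sub = query[lo:hi]
        alignments = aligner.align(sub, target)
        if alignments.score < params.min_score:
            return
        best = alignments[0]
        results.append(_from_biopython(best, sub, target, lo))
        recurse(lo, lo + int(best.coordinates[0, 0]))
        recurse(lo + int(best.coordinates[0, -1]), hi)

    recurse(0, len(query))
    results.sort(key=lambda a: (-a.score, a.query_start))
    return results[: params.max_alignments]
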