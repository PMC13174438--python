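"""Residue-level mapping: run classification, connectivity-based alignment
refinement, segment generation and one-to-one residue correspondences.

Pairwise sequence alignment can place short, isolated matches inside long
gaps (typically across unresolved regions), fragmenting what is physically
one continuous gap.  Refinement classifies aligned runs, checks observed
backbone geometry (the carbonyl C of one residue to the amide N of the
next, connected strictly below 1.42 Å by default) and either merges an
isolated run into the neighbouring continuous region (when physically
connected) or un-aligns it so the gap becomes one contiguous block.
"""
from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
from Bio.Align import substitution_matrices

from .align import AlignerParams, LocalAlignment, local_alignments  # noqa: F401
from .ccd import ComponentDictionary, backbone_atom_names
from .errors import ConsistencyError, InputError
from .mmcif_io import ChainInstance, ResidueRecord
from .reference_db import ReferenceRecord
from .residues import is_standard
from .scoring import ScoredHit

__all__ = [
    "RefinementParams",
    "Segment",
    "ResidueXref",
    "LocalAlignment",
    "local_alignments",
    "resolve_backbone_atoms",
    "is_connected",
    "classify_runs",
    "refine_alignment",
    "build_segments",
    "residue_mapping",
    "mark_chimera",
    "CONTINUOUS",
    "ISOLATED",
    "GAP",
    "EXTENDED_GAP",
]

# column labels
CONTINUOUS = "continuous"
ISOLATED = "isolated"
GAP = "gap"
EXTENDED_GAP = "extended_gap"


@dataclass
class RefinementParams:
    """Connectivity and run-length thresholds for alignment refinement.

    Aligned runs strictly shorter than ``isolated_max_run`` and bounded by
    extended gaps are refinement candidates; runs of ``continuous_min_run``
    or more are always protected.  Connectivity is strict: a C–N distance
    exactly at ``connect_threshold`` is *not* connected.
    """

    connect_threshold: float = 1.42
    isolated_max_run: int = 5
    continuous_min_run: int = 5

    def __post_init__(self):
        if self.connect_threshold <= 0:
            raise InputError("connect_threshold must be positive")
        if self.isolated_max_run > self.continuous_min_run + 1:
            raise InputError(
                "isolated_max_run must not exceed continuous_min_run + 1"
            )


@dataclass
class Segment:
    """A continuous aligned block mapping structure residues to a reference."""

    entry: str
    entity: str
    auth_asym_id: str
    struct_asym_id: str
    accession: str
    name: str
    seq_version: int
    query_start: int
    query_end: int
    target_start: int
    target_end: int
    auth_start: int
    auth_end: int
    auth_code: str
    target_alignment: str
    query_alignment: str
    identity: float
    score: float
    conflicts: int
    modifications: int
    best_mapping: bool
    canonical_acc: bool
    chimera: bool = False
    tax_id: int = 0


@dataclass
class ResidueXref:
    """One residue's final correspondence to a reference-sequence position."""

    entry: str
    entity: str
    auth_asym_id: str
    struct_asym_id: str
    target_segment_id: int
    auth_seq_id: int
    auth_seq_id_ins_code: str
    query_seq_id: int
    target_seq_id: int
    observed: bool
    query_one_letter_code: str
    target_one_letter_code: str
    chem_comp_id: str
    type: str
    tax_id: int
    best_mapping: bool
    canonical_acc: bool
    residue_id: int
    accession: str = ""


def resolve_backbone_atoms(
    chem_comp_id: str, ccd: ComponentDictionary | None = None
) -> tuple[str, str]:
    """Names of the backbone (amide N, carbonyl C) atoms for a component."""
    return backbone_atom_names(chem_comp_id, ccd)


def is_connected(
    prev: ResidueRecord,
    next: ResidueRecord,
    params: RefinementParams | None = None,
) -> bool:
    """True iff |C(prev) - N(next)| < connect_threshold (strict).

    Unobserved residues or missing backbone atoms are never connected.
    """
    params = params or RefinementParams()
    if not prev.observed or not next.observed:
        return False
    if prev.c_coord is None or next.n_coord is None:
        return False
    distance = float(np.linalg.norm(prev.c_coord - next.n_coord))
    return distance < params.connect_threshold


# ---------------------------------------------------------------------------
# run classification


def _runs(columns: Sequence[tuple[str, str]]) -> list[tuple[bool, int, int]]:
    """Maximal runs of (is_aligned, start, end_inclusive) column indices."""
    runs = []
    for i, (q, t) in enumerate(columns):
        aligned = q != "-" and t != "-"
        if runs and runs[-1][0] == aligned:
            runs[-1][2] = i
        else:
            runs.append([aligned, i, i])
    return [tuple(r) for r in runs]


def classify_runs(
    alignment: LocalAlignment, params: RefinementParams | None = None
) -> list[str]:
    """Label every alignment column.

    Aligned columns become ``continuous`` or ``isolated``; gap columns
    become ``gap`` (single) or ``extended_gap`` (more than one consecutive
    gap symbol).  An aligned run is isolated when it is strictly shorter
    than ``isolated_max_run`` and bounded by extended gaps on both sides.
    """
    params = params or RefinementParams()
    columns = alignment.columns
    runs = _runs(columns)
    labels = [""] * len(columns)
    for idx, (aligned, start, end) in enumerate(runs):
        length = end - start + 1
        if not aligned:
            label = EXTENDED_GAP if length > 1 else GAP
        else:
            left_extended = (
                idx > 0
                and not runs[idx - 1][0]
                and runs[idx - 1][2] - runs[idx - 1][1] + 1 > 1
            )
            right_extended = (
                idx < len(runs) - 1
                and not runs[idx + 1][0]
                and runs[idx + 1][2] - runs[idx + 1][1] + 1 > 1
            )
            if length < params.isolated_max_run and left_extended and right_extended:
                label = ISOLATED
            else:
                label = CONTINUOUS
        for i in range(start, end + 1):
            labels[i] = label
    return labels


# ---------------------------------------------------------------------------
# refinement


def _query_positions(columns, query_start: int) -> list[int | None]:
    """Per-column query position (None on query-gap columns)."""
    positions: list[int | None] = []
    pos = query_start
    for q, _ in columns:
        if q != "-":
            positions.append(pos)
            pos += 1
        else:
            positions.append(None)
    return positions


def _score_columns(
    columns: Sequence[tuple[str, str]], params: AlignerParams
) -> float:
    matrix = substitution_matrices.load(params.matrix_name)
    score = 0.0
    in_gap = False
    for q, t in columns:
        if q == "-" or t == "-":
            score -= params.gap_extend + (0.0 if in_gap else params.gap_open)
            in_gap = True
        else:
            score += matrix[q, t]
            in_gap = False
    return score


def refine_alignment(
    alignment: LocalAlignment,
    chain: ChainInstance,
    params: RefinementParams | None = None,
) -> tuple[LocalAlignment, list[dict]]:
    """Resolve isolated aligned runs against observed backbone connectivity.

    Each isolated run is merged into the adjacent continuous region when
    its terminal residue is backbone-connected to that region's facing
    terminal residue (preceding region checked first), and un-aligned
    otherwise, leaving the surrounding gap as one contiguous block.
    Continuous columns are never altered; the returned audit log records
    one action per isolated run.  The operation is idempotent.
    """
    params = params or RefinementParams()
    columns = alignment.columns
    audit: list[dict] = []
    merged: set[tuple[int, int]] = set()

    while True:
        labels = _label_columns(columns, params)
        positions = _query_positions(columns, alignment.query_start)
        action = _next_action(columns, labels, positions, chain, params, merged)
        if action is None:
            break
        kind, run_span, region_span, detail = action
        first_q = positions[run_span[0]]
        last_q = positions[run_span[1]]
        if kind == "merge":
            merged.add((first_q, last_q))
            audit.append(
                {"action": "merge", "query_range": (first_q, last_q), **detail}
            )
            continue
        # un-align: region = left gap run + isolated run + right gap run
        lo, hi = region_span
        region = columns[lo : hi + 1]
        query_letters = [q for q, _ in region if q != "-"]
        target_letters = [t for _, t in region if t != "-"]
        replacement = [(q, "-") for q in query_letters] + [
            ("-", t) for t in target_letters
        ]
        columns = columns[:lo] + replacement + columns[hi + 1 :]
        audit.append(
            {"action": "unalign", "query_range": (first_q, last_q), **detail}
        )

    refined = replace(
        alignment,
        query_aligned="".join(q for q, _ in columns),
        target_aligned="".join(t for _, t in columns),
    )
    refined.recompute_identity()
    return refined, audit


def _label_columns(columns, params) -> list[str]:
    probe = LocalAlignment(
        query_aligned="".join(q for q, _ in columns),
        target_aligned="".join(t for _, t in columns),
        query_start=1,
        query_end=max(1, sum(1 for q, _ in columns if q != "-")),
        target_start=1,
        target_end=max(1, sum(1 for _, t in columns if t != "-")),
        score=0.0,
    )
    return classify_runs(probe, params)


def _next_action(columns, labels, positions, chain, params, merged):
    """Find the next isolated run to act on, or None when refinement is done.

    Returns (kind, run_span, region_span, detail) where spans are inclusive
    column index pairs.
    """
    runs = _runs(columns)
    run_label = {(start, end): labels[start] for _, start, end in runs}
    for idx, (aligned, start, end) in enumerate(runs):
        if not aligned or run_label[(start, end)] != ISOLATED:
            continue
        first_q = positions[start]
        last_q = positions[end]
        if (first_q, last_q) in merged:
            continue
        prev_region = _nearest_continuous(runs, labels, idx, direction=-1)
        next_region = _nearest_continuous(runs, labels, idx, direction=+1)
        connected_prev = False
        connected_next = False
        if prev_region is not None:
            prev_q = positions[prev_region[1]]
            connected_prev = is_connected(
                chain.residue_by_label(prev_q),
                chain.residue_by_label(first_q),
                params,
            )
        if next_region is not None:
            next_q = positions[next_region[0]]
            connected_next = is_connected(
                chain.residue_by_label(last_q),
                chain.residue_by_label(next_q),
                params,
            )
        detail = {
            "connected_prev": connected_prev,
            "connected_next": connected_next,
            "run_length": end - start + 1,
        }
        if connected_prev or connected_next:
            return "merge", (start, end), (start, end), detail
        region_lo = runs[idx - 1][1]  # bounding gap runs exist by definition
        region_hi = runs[idx + 1][2]
        return "unalign", (start, end), (region_lo, region_hi), detail
    return None


def _nearest_continuous(runs, labels, idx, direction):
    j = idx + direction
    while 0 <= j < len(runs):
        aligned, start, end = runs[j]
        if aligned and labels[start] == CONTINUOUS:
            return (start, end)
        j += direction
    return None


# ---------------------------------------------------------------------------
# segments and residue rows


def build_segments(
    chain: ChainInstance,
    alignments: Sequence[LocalAlignment],
    hit: ScoredHit | None,
    reference: ReferenceRecord,
    params: RefinementParams | None = None,
    entry: str = "",
    entity: str = "",
    aligner_params: AlignerParams | None = None,
) -> list[Segment]:
    """Cut refined alignments into maximal connectivity-consistent segments.

    A segment breaks wherever two consecutive *observed* chain residues
    inside the aligned span fail the backbone connectivity check; pairs
    involving unobserved residues cannot be evaluated and never split.
    """
    params = params or RefinementParams()
    aligner_params = aligner_params or AlignerParams()
    ordered = sorted(alignments, key=lambda a: a.query_start)
    for left, right in zip(ordered, ordered[1:]):
        if left.query_end >= right.query_start:
            raise ConsistencyError(
                f"alignments overlap on the query: "
                f"{left.query_start}-{left.query_end} vs "
                f"{right.query_start}-{right.query_end}"
            )

    if hit is not None:
        entry = entry or hit.entry
        entity = entity or hit.entity
    best = hit is None or hit.hit_rank == 1
    canonical = "-" not in reference.accession

    segments: list[Segment] = []
    for alignment in ordered:
        columns = alignment.columns
        positions = _query_positions(columns, alignment.query_start)
        target_positions = _target_positions(columns, alignment.target_start)
        aligned_idx = [
            i for i, (q, t) in enumerate(columns) if q != "-" and t != "-"
        ]
        if not aligned_idx:
            continue
        groups: list[list[int]] = [[aligned_idx[0]]]
        for prev_i, cur_i in zip(aligned_idx, aligned_idx[1:]):
            if _has_break(chain, positions[prev_i], positions[cur_i], params):
                groups.append([cur_i])
            else:
                groups[-1].append(cur_i)
        for group in groups:
            lo, hi = group[0], group[-1]
            span = columns[lo : hi + 1]
            aligned_span = [(q, t) for q, t in span if q != "-" and t != "-"]
            identical = sum(1 for q, t in aligned_span if q == t)
            conflicts = len(aligned_span) - identical
            q_start = positions[lo]
            q_end = positions[hi]
            modifications = sum(
                1
                for i in group
                if not is_standard(
                    chain.residue_by_label(positions[i]).chem_comp_id
                )
            )
            start_res = chain.residue_by_label(q_start)
            end_res = chain.residue_by_label(q_end)
            segments.append(
                Segment(
                    entry=entry,
                    entity=entity,
                    auth_asym_id=chain.auth_asym_id,
                    struct_asym_id=chain.struct_asym_id,
                    accession=reference.accession,
                    name=reference.name,
                    seq_version=reference.seq_version,
                    query_start=q_start,
                    query_end=q_end,
                    target_start=target_positions[lo],
                    target_end=target_positions[hi],
                    auth_start=start_res.auth_seq_id,
                    auth_end=end_res.auth_seq_id,
                    auth_code=start_res.ins_code,
                    target_alignment="".join(t for _, t in span),
                    query_alignment="".join(q for q, _ in span),
                    identity=identical / len(span) if span else 0.0,
                    score=_score_columns(span, aligner_params),
                    conflicts=conflicts,
                    modifications=modifications,
                    best_mapping=best,
                    canonical_acc=canonical,
                    chimera=False,
                    tax_id=reference.tax_id,
                )
            )
    return segments


def _target_positions(columns, target_start: int) -> list[int | None]:
    positions: list[int | None] = []
    pos = target_start
    for _, t in columns:
        if t != "-":
            positions.append(pos)
            pos += 1
        else:
            positions.append(None)
    return positions


def _has_break(chain, q_from: int, q_to: int, params) -> bool:
    for label in range(q_from, q_to):
        prev = chain.residue_by_label(label)
        next_ = chain.residue_by_label(label + 1)
        if prev.observed and next_.observed and not is_connected(prev, next_, params):
            return True
    return False


def mark_chimera(segments: Iterable[Segment]) -> None:
    """Set chimera=True on every segment of entities mapped to >= 2 accessions."""
    by_entity: dict[tuple[str, str], set[str]] = {}
    for seg in segments:
        by_entity.setdefault((seg.entry, seg.entity), set()).add(seg.accession)
    for seg in segments:
        seg.chimera = len(by_entity[(seg.entry, seg.entity)]) >= 2


def residue_mapping(
    segments: Sequence[Segment], chain: ChainInstance
) -> list[ResidueXref]:
    """One row per aligned residue of every segment.

    Unobserved residues are mapped (``observed=False``): mapping operates
    on the sample sequence, not on coordinate completeness.  Within the
    best mapping the query-to-target correspondence must be injective.
    """
    rows: list[ResidueXref] = []
    best_targets: dict[str, set[int]] = {}
    for segment_id, segment in enumerate(segments, start=1):
        columns = list(zip(segment.query_alignment, segment.target_alignment))
        q_pos = segment.query_start
        t_pos = segment.target_start
        for q, t in columns:
            if q != "-" and t != "-":
                residue = chain.residue_by_label(q_pos)
                rows.append(
                    ResidueXref(
                        entry=segment.entry,
                        entity=segment.entity,
                        auth_asym_id=segment.auth_asym_id,
                        struct_asym_id=segment.struct_asym_id,
                        target_segment_id=segment_id,
                        auth_seq_id=residue.auth_seq_id,
                        auth_seq_id_ins_code=residue.ins_code,
                        query_seq_id=q_pos,
                        target_seq_id=t_pos,
                        observed=residue.observed,
                        query_one_letter_code=residue.one_letter,
                        target_one_letter_code=t,
                        chem_comp_id=residue.chem_comp_id,
                        type="polypeptide",
                        tax_id=segment.tax_id,
                        best_mapping=segment.best_mapping,
                        canonical_acc=segment.canonical_acc,
                        residue_id=residue.label_seq_id,
                        accession=segment.accession,
                    )
                )
                if segment.best_mapping:
                    targets = best_targets.setdefault(segment.accession, set())
                    if t_pos in targets:
                        raise ConsistencyError(
                            f"best mapping is not injective: reference residue "
                            f"{t_pos} of {segment.accession} mapped twice"
                        )
                    targets.add(t_pos)
            if q != "-":
                q_pos += 1
            if t != "-":
                t_pos += 1
    return rows
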