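import random

import pytest

from siftsmap.align import AlignerParams, LocalAlignment, local_alignments
from siftsmap.errors import ConsistencyError
from siftsmap.fixtures import (
    StructureSpec,
    make_isolated_artifact_case,
    make_toy_structure,
)
from siftsmap.mmcif_io import parse_polymer_entities
from siftsmap.reference_db import ReferenceRecord
from siftsmap.residues import STANDARD_AA
from siftsmap.segmenter import (
    CONTINUOUS,
    EXTENDED_GAP,
    GAP,
    ISOLATED,
    RefinementParams,
    build_segments,
    classify_runs,
    is_connected,
    mark_chimera,
    refine_alignment,
    residue_mapping,
)


def make_alignment(query_aligned, target_aligned, query_start=1, target_start=1):
    query_len = sum(1 for c in query_aligned if c != "-")
    target_len = sum(1 for c in target_aligned if c != "-")
    alignment = LocalAlignment(
        query_aligned=query_aligned,
        target_aligned=target_aligned,
        query_start=query_start,
        query_end=query_start + query_len - 1,
        target_start=target_start,
        target_end=target_start + target_len - 1,
        score=0.0,
    )
    alignment.recompute_identity()
    return alignment


def chain_of(sequence, **kwargs):
    cif = make_toy_structure(StructureSpec(sequence=sequence, **kwargs))
    return parse_polymer_entities(cif)[0].chains[0]


def make_ref(sequence, accession="P90001", tax_id=101, dataset="reviewed"):
    return ReferenceRecord(
        accession=accession, name="TST_SYNTH", seq_version=1,
        sequence=sequence, dataset=dataset, tax_id=tax_id,
    )


# ---------------------------------------------------------------------------
# connectivity


def test_connected_at_peptide_bond_distance():
    chain = chain_of("ACDEFGHIKL")
    assert is_connected(chain.residues[0], chain.residues[1])


def test_not_connected_exactly_at_threshold():
    chain = chain_of("ACDEFGHIKL", breaks=[(3, 1.42)])
    assert not is_connected(chain.residues[2], chain.residues[3])


def test_just_below_threshold_is_connected():
    chain = chain_of("ACDEFGHIKL", breaks=[(3, 1.4199999)])
    assert is_connected(chain.residues[2], chain.residues[3])


def test_unobserved_never_connected():
    chain = chain_of("ACDEFGHIKL", observed=[True] * 5 + [False] + [True] * 4)
    assert not is_connected(chain.residues[4], chain.residues[5])
    assert not is_connected(chain.residues[5], chain.residues[6])


def test_connectivity_boundary_by_sweep():
    params = RefinementParams()
    distances = [1.0 + 0.05 * i for i in range(21)]
    states = []
    for distance in distances:
        chain = chain_of("ACDEF", breaks=[(2, distance)])
        states.append(is_connected(chain.residues[1], chain.residues[2], params))
    # single transition, exactly at the threshold
    transitions = [
        distances[i + 1] for i in range(len(states) - 1)
        if states[i] and not states[i + 1]
    ]
    assert len(transitions) == 1
    assert all(s for d, s in zip(distances, states) if d < 1.42)
    assert not any(s for d, s in zip(distances, states) if d >= 1.42)


# ---------------------------------------------------------------------------
# run classification


def test_classify_two_continuous_one_extended_gap():
    alignment = make_alignment(
        "A" * 12 + "-" * 6 + "C" * 12,
        "A" * 12 + "W" * 6 + "C" * 12,
    )
    labels = classify_runs(alignment)
    assert labels[:12] == [CONTINUOUS] * 12
    assert labels[12:18] == [EXTENDED_GAP] * 6
    assert labels[18:] == [CONTINUOUS] * 12


def test_classify_lone_residue_between_extended_gaps_is_isolated():
    alignment = make_alignment(
        "A" * 10 + "-" * 4 + "G" + "-" * 5 + "C" * 10,
        "A" * 10 + "W" * 4 + "G" + "W" * 5 + "C" * 10,
    )
    labels = classify_runs(alignment)
    assert labels[14] == ISOLATED
    assert labels[10:14] == [EXTENDED_GAP] * 4
    assert labels[15:20] == [EXTENDED_GAP] * 5


def test_classify_six_residue_run_is_continuous():
    alignment = make_alignment(
        "A" * 10 + "-" * 4 + "G" * 6 + "-" * 5 + "C" * 10,
        "A" * 10 + "W" * 4 + "G" * 6 + "W" * 5 + "C" * 10,
    )
    labels = classify_runs(alignment)
    assert set(labels[14:20]) == {CONTINUOUS}


def test_classify_run_of_exactly_five_is_protected():
    alignment = make_alignment(
        "A" * 10 + "-" * 4 + "G" * 5 + "-" * 5 + "C" * 10,
        "A" * 10 + "W" * 4 + "G" * 5 + "W" * 5 + "C" * 10,
    )
    labels = classify_runs(alignment)
    assert set(labels[14:19]) == {CONTINUOUS}


def test_classify_single_gap_column_is_not_extended():
    alignment = make_alignment("AAAA-AAAA", "AAAACAAAA")
    labels = classify_runs(alignment)
    assert labels[4] == GAP
    assert labels.count(CONTINUOUS) == 8


def test_classify_short_run_at_alignment_edge_is_continuous():
    # bounded by the alignment edge, not by an extended gap
    alignment = make_alignment(
        "AG" + "-" * 4 + "C" * 10,
        "AG" + "W" * 4 + "C" * 10,
    )
    labels = classify_runs(alignment)
    assert labels[0] == CONTINUOUS and labels[1] == CONTINUOUS


# ---------------------------------------------------------------------------
# refinement


def _isolated_fixture(observed_isolated: bool, break_before=None):
    """Chain AAAAAAAAAA G CCCCCCCCCC aligned to a reference with 9 extra
    residues around the lone G."""
    sequence = "A" * 10 + "G" + "C" * 10
    observed = [True] * 21
    if not observed_isolated:
        observed[10] = False
    breaks = []
    if break_before is not None:
        breaks.append(break_before)
    chain = chain_of(sequence, observed=observed, breaks=breaks)
    alignment = make_alignment(
        "A" * 10 + "----" + "G" + "-----" + "C" * 10,
        "A" * 10 + "WWWW" + "G" + "WWWWW" + "C" * 10,
    )
    return chain, alignment


def test_refine_unaligns_unobserved_isolated_run():
    chain, alignment = _isolated_fixture(observed_isolated=False)
    refined, audit = refine_alignment(alignment, chain)
    assert [a["action"] for a in audit] == ["unalign"]
    labels = classify_runs(refined)
    assert ISOLATED not in labels
    # the query letters are preserved, the gap is one contiguous block
    assert refined.query_aligned.replace("-", "") == alignment.query_aligned.replace("-", "")
    assert refined.target_aligned.replace("-", "") == alignment.target_aligned.replace("-", "")
    assert "G" + "-" * 10 in refined.query_aligned


def test_refine_merges_connected_isolated_run():
    # G physically connected to both flanks: kept, labelled merge
    chain, alignment = _isolated_fixture(observed_isolated=True)
    refined, audit = refine_alignment(alignment, chain)
    assert [a["action"] for a in audit] == ["merge"]
    assert audit[0]["connected_prev"]
    assert refined.query_aligned == alignment.query_aligned
    assert refined.target_aligned == alignment.target_aligned


def test_refine_unaligns_observed_but_disconnected_run():
    # observed G with physical breaks on both sides: still an artefact
    chain, alignment = _isolated_fixture(
        observed_isolated=True, break_before=(10, 5.0)
    )
    # also break after the G
    sequence = "A" * 10 + "G" + "C" * 10
    chain = chain_of(sequence, breaks=[(10, 5.0), (11, 5.0)])
    refined, audit = refine_alignment(alignment, chain)
    assert [a["action"] for a in audit] == ["unalign"]


def test_refine_no_extended_gaps_is_identity():
    chain = chain_of("ACDEFGHIKL")
    alignment = make_alignment("ACDEFGHIKL", "ACDEFGHIKL")
    refined, audit = refine_alignment(alignment, chain)
    assert audit == []
    assert refined.query_aligned == alignment.query_aligned


def test_refine_idempotent():
    for observed in (True, False):
        chain, alignment = _isolated_fixture(observed_isolated=observed)
        once, _ = refine_alignment(alignment, chain)
        twice, audit2 = refine_alignment(once, chain)
        assert twice.query_aligned == once.query_aligned
        assert twice.target_aligned == once.target_aligned


def test_refine_never_touches_continuous_columns():
    chain, alignment = _isolated_fixture(observed_isolated=False)
    labels = classify_runs(alignment)
    refined, _ = refine_alignment(alignment, chain)
    before = [c for c, l in zip(alignment.columns, labels) if l == CONTINUOUS]
    after_cols = refined.columns
    # every continuous column survives unchanged, in order
    iterator = iter(after_cols)
    for column in before:
        for candidate in iterator:
            if candidate == column:
                break
        else:
            pytest.fail(f"continuous column {column} lost by refinement")


def test_refine_generated_artifact_end_to_end():
    case = make_isolated_artifact_case(seed=2)
    chain = parse_polymer_entities(case.structure_cif)[0].chains[0]
    alignments = local_alignments(case.query_sequence, case.reference_sequence)
    assert len(alignments) == 1
    labels = classify_runs(alignments[0])
    assert ISOLATED in labels
    refined, audit = refine_alignment(alignments[0], chain)
    assert [a["action"] for a in audit] == ["unalign"]
    refined_labels = classify_runs(refined)
    assert ISOLATED not in refined_labels
    # unresolved region is one contiguous unmapped block
    gap_blocks = [
        block for block in refined.query_aligned.split("W") if "-" in block
    ]
    assert len(gap_blocks) == 1


# ---------------------------------------------------------------------------
# segments


def test_single_segment_for_connected_chain():
    sequence = "ACDEFGHIKLMNPQRSTVWY"
    chain = chain_of(sequence)
    alignment = make_alignment(sequence, sequence)
    segments = build_segments(chain, [alignment], None, make_ref(sequence),
                              entry="toy1", entity="1")
    assert len(segments) == 1
    segment = segments[0]
    assert (segment.query_start, segment.query_end) == (1, 20)
    assert (segment.target_start, segment.target_end) == (1, 20)
    assert segment.identity == 1.0
    assert segment.conflicts == 0
    assert segment.best_mapping and segment.canonical_acc and not segment.chimera


def test_physical_break_splits_segment():
    sequence = "ACDEFGHIKLMNPQRSTVWY"
    chain = chain_of(sequence, breaks=[(10, 4.0)])
    alignment = make_alignment(sequence, sequence)
    segments = build_segments(chain, [alignment], None, make_ref(sequence),
                              entry="toy1", entity="1")
    assert len(segments) == 2
    assert (segments[0].query_start, segments[0].query_end) == (1, 10)
    assert (segments[1].query_start, segments[1].query_end) == (11, 20)


def test_unobserved_loop_does_not_split_segment():
    sequence = "ACDEFGHIKLMNPQRSTVWY"
    observed = [True] * 8 + [False] * 4 + [True] * 8
    chain = chain_of(sequence, observed=observed)
    alignment = make_alignment(sequence, sequence)
    segments = build_segments(chain, [alignment], None, make_ref(sequence),
                              entry="toy1", entity="1")
    assert len(segments) == 1


def test_overlapping_alignments_rejected():
    sequence = "ACDEFGHIKL"
    chain = chain_of(sequence)
    a1 = make_alignment(sequence[:6], sequence[:6], query_start=1)
    a2 = make_alignment(sequence[4:], sequence[4:], query_start=5)
    with pytest.raises(ConsistencyError):
        build_segments(chain, [a1, a2], None, make_ref(sequence),
                       entry="toy1", entity="1")


def test_chimera_flag_for_two_accessions():
    sequence = "ACDEFGHIKLMNPQRSTVWY"
    chain = chain_of(sequence)
    left = make_alignment(sequence[:10], sequence[:10], query_start=1)
    right = make_alignment(sequence[10:], sequence[10:], query_start=11)
    seg_a = build_segments(chain, [left], None,
                           make_ref(sequence[:10], accession="P90001"),
                           entry="toy1", entity="1")
    seg_b = build_segments(chain, [right], None,
                           make_ref(sequence[10:], accession="P90002"),
                           entry="toy1", entity="1")
    segments = seg_a + seg_b
    mark_chimera(segments)
    assert all(s.chimera for s in segments)


def test_isoform_accession_not_canonical():
    sequence = "ACDEFGHIKL"
    chain = chain_of(sequence)
    alignment = make_alignment(sequence, sequence)
    segments = build_segments(chain, [alignment], None,
                              make_ref(sequence, accession="P90001-2"),
                              entry="toy1", entity="1")
    assert not segments[0].canonical_acc


def test_modifications_counted(toy_ccd):
    sequence = "AMCDE"
    cif = make_toy_structure(StructureSpec(sequence=sequence, modified={2: "MSE"}))
    chain = parse_polymer_entities(cif, toy_ccd)[0].chains[0]
    alignment = make_alignment(sequence, sequence)
    segments = build_segments(chain, [alignment], None, make_ref(sequence),
                              entry="toy1", entity="1")
    assert segments[0].modifications == 1
    assert segments[0].conflicts == 0


# ---------------------------------------------------------------------------
# residue mapping


def test_identity_residue_mapping():
    sequence = "ACDEFGHIKL"
    chain = chain_of(sequence)
    alignment = make_alignment(sequence, sequence)
    segments = build_segments(chain, [alignment], None, make_ref(sequence),
                              entry="toy1", entity="1")
    rows = residue_mapping(segments, chain)
    assert len(rows) == 10
    assert all(r.query_seq_id == r.target_seq_id for r in rows)
    assert all(r.observed for r in rows)


def test_numbering_offset_mapping():
    # reference has one extra leading residue: structure residue with auth
    # number 116 maps to reference residue 117
    sequence = "".join(
        random.Random(0).choice(STANDARD_AA) for _ in range(120)
    )
    reference_seq = "M" + sequence
    chain = chain_of(sequence, auth_offset=0)
    alignment = make_alignment(sequence, reference_seq[1:], target_start=2)
    segments = build_segments(chain, [alignment], None, make_ref(reference_seq),
                              entry="toy1", entity="1")
    rows = residue_mapping(segments, chain)
    by_auth = {r.auth_seq_id: r for r in rows}
    assert by_auth[116].target_seq_id == 117
    assert all(r.target_seq_id == r.query_seq_id + 1 for r in rows)


def test_unobserved_loop_rows_present():
    sequence = "ACDEFGHIKLMNPQRSTVWY"
    observed = [True] * 8 + [False] * 4 + [True] * 8
    chain = chain_of(sequence, observed=observed)
    alignment = make_alignment(sequence, sequence)
    segments = build_segments(chain, [alignment], None, make_ref(sequence),
                              entry="toy1", entity="1")
    rows = residue_mapping(segments, chain)
    assert len(rows) == 20
    assert [not r.observed for r in rows].count(True) == 4


def test_rows_lie_inside_exactly_one_segment():
    case = make_isolated_artifact_case(seed=3)
    chain = parse_polymer_entities(case.structure_cif)[0].chains[0]
    alignments = local_alignments(case.query_sequence, case.reference_sequence)
    refined, _ = refine_alignment(alignments[0], chain)
    segments = build_segments(chain, [refined], None,
                              make_ref(case.reference_sequence),
                              entry="art1", entity="1")
    rows = residue_mapping(segments, chain)
    for row in rows:
        containing = [
            i for i, s in enumerate(segments, start=1)
            if s.query_start <= row.query_seq_id <= s.query_end
        ]
        assert containing == [row.target_segment_id]
    # injectivity of the best mapping
    targets = [r.target_seq_id for r in rows if r.best_mapping]
    assert len(targets) == len(set(targets))
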