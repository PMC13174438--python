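"""Composite hit scoring and deterministic ranking.

The score of a candidate hit combines four bounded components:

* ``base_score``      — coverage x identity x 1000
* ``mismatch_penalty``— 1 - mismatches / query_length
* ``taxonomy_score``  — +200 species, +100 genus, +50 family, +25 order
* ``provenance score``— reviewed: +20 x annotation score;
                        unreviewed: -50 + 10 x annotation score; other: 0

giving a total in [-50, 1300].  PDB cross-reference counts break ties in
the ranking but never contribute to the score itself, keeping the score
bounded and comparable across proteins.
"""
from __future__ import annotations

import os
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .errors import InputError
from .reference_db import RawHit, ReferenceRecord

__all__ = [
    "LineageRecord",
    "ScoredHit",
    "load_lineage_table",
    "base_score",
    "mismatch_penalty",
    "taxonomy_score",
    "provenance_score",
    "sifts_score",
    "rank_hits",
    "write_hits_tsv",
    "HITS_TSV_COLUMNS",
]

SCORE_MIN = -50.0
SCORE_MAX = 1300.0

TAX_SPECIES = 200
TAX_GENUS = 100
TAX_FAMILY = 50
TAX_ORDER = 25


@dataclass(frozen=True)
class LineageRecord:
    """Rank-annotated lineage of one taxon; absent ranks are None."""

    tax_id: int
    species_taxid: int | None = None
    genus_taxid: int | None = None
    family_taxid: int | None = None
    order_taxid: int | None = None


def load_lineage_table(path: str | os.PathLike) -> dict[int, LineageRecord]:
    """Read ``taxid<TAB>species<TAB>genus<TAB>family<TAB>order`` (blank = absent)."""
    table: dict[int, LineageRecord] = {}
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 5:
                raise InputError(f"lineage table line {line_no}: expected 5 columns")
            values = [int(p) if p.strip() else None for p in parts]
            if values[0] is None:
                raise InputError(f"lineage table line {line_no}: missing taxid")
            table[values[0]] = LineageRecord(
                tax_id=values[0],
                species_taxid=values[1],
                genus_taxid=values[2],
                family_taxid=values[3],
                order_taxid=values[4],
            )
    return table


@dataclass
class ScoredHit:
    hit: RawHit
    base_score: float
    mismatch_penalty: float
    adjusted_score: float
    tax_score: int
    dataset_score: int
    sifts_score: float
    pdb_cross_references: int
    hit_rank: int = 0

    def __getattr__(self, name):
        # transparent access to the underlying RawHit fields
        if name.startswith("_") or name == "hit":
            raise AttributeError(name)
        return getattr(self.hit, name)


def base_score(coverage: float, identity: float) -> float:
    """Coverage x identity scaled to [0, 1000]."""
    if not 0.0 <= coverage <= 1.0:
        raise InputError(f"coverage {coverage} outside [0, 1]")
    if not 0.0 <= identity <= 1.0:
        raise InputError(f"identity {identity} outside [0, 1]")
    return coverage * identity * 1000.0


def mismatch_penalty(mismatches: int, query_len: int) -> float:
    """1 - mismatches / query length; short queries are penalised harder."""
    if query_len <= 0:
        raise InputError("query length must be positive")
    if not 0 <= mismatches <= query_len:
        raise InputError(
            f"mismatch count {mismatches} outside [0, query_len={query_len}]"
        )
    return 1.0 - mismatches / query_len


def taxonomy_score(
    query_tax: int,
    target_tax: int,
    lineages: Mapping[int, LineageRecord],
) -> int:
    """Shared-rank bonus: species 200, genus 100, family 50, order 25, else 0.

    Identical taxids score the full species bonus.  Missing lineage records
    degrade to 0 with a warning; ranks absent on either side never match.
    """
    if query_tax == target_tax:
        return TAX_SPECIES
    query_lineage = lineages.get(query_tax)
    target_lineage = lineages.get(target_tax)
    if query_lineage is None or target_lineage is None:
        missing = [
            t for t, lineage in ((query_tax, query_lineage), (target_tax, target_lineage))
            if lineage is None
        ]
        warnings.warn(
            f"no lineage record for taxid(s) {missing}; taxonomy score is 0",
            stacklevel=2,
        )
        return 0
    for rank, points in (
        ("species_taxid", TAX_SPECIES),
        ("genus_taxid", TAX_GENUS),
        ("family_taxid", TAX_FAMILY),
        ("order_taxid", TAX_ORDER),
    ):
        query_rank = getattr(query_lineage, rank)
        target_rank = getattr(target_lineage, rank)
        if query_rank is not None and query_rank == target_rank:
            return points
    return 0


def provenance_score(dataset: str, annotation_score: int) -> int:
    """Reviewed: +20 x score; unreviewed: -50 + 10 x score; other: 0."""
    if not isinstance(annotation_score, int) or not 0 <= annotation_score <= 5:
        raise InputError(f"annotation score {annotation_score!r} outside 0..5")
    if dataset == "reviewed":
        return 20 * annotation_score
    if dataset == "unreviewed":
        return -50 + 10 * annotation_score
    if dataset == "other":
        return 0
    raise InputError(f"unknown dataset {dataset!r}")


def sifts_score(
    hit: RawHit,
    lineages: Mapping[int, LineageRecord],
    reference: ReferenceRecord,
) -> ScoredHit:
    """Score one hit; the result is guaranteed to lie in [-50, 1300]."""
    base = base_score(hit.coverage, hit.identity)
    penalty = mismatch_penalty(hit.mismatch, hit.query_len)
    adjusted = base * penalty
    tax = taxonomy_score(hit.query_tax_id, hit.target_tax_id, lineages)
    dataset = provenance_score(reference.dataset, reference.annotation_score)
    total = adjusted + tax + dataset
    if not SCORE_MIN <= total <= SCORE_MAX:
        raise InputError(f"composite score {total} escaped [-50, 1300]")
    return ScoredHit(
        hit=hit,
        base_score=base,
        mismatch_penalty=penalty,
        adjusted_score=adjusted,
        tax_score=tax,
        dataset_score=dataset,
        sifts_score=total,
        pdb_cross_references=reference.pdb_xref_count,
    )


def rank_hits(hits: Sequence[ScoredHit]) -> list[ScoredHit]:
    """Deterministic total order: score desc, PDB cross-references desc,
    accession asc.  ``hit_rank`` is assigned 1..n (rank 1 = best mapping)."""
    ordered = sorted(
        hits,
        key=lambda h: (-h.sifts_score, -h.pdb_cross_references, h.hit.accession),
    )
    for rank, hit in enumerate(ordered, start=1):
        hit.hit_rank = rank
    return ordered


#: column order of the ranked-hits TSV (and the hits database table)
HITS_TSV_COLUMNS = (
    "entry", "entity", "accession", "alignment_len", "query_len", "mismatch",
    "query_start", "query_end", "target_start", "target_end", "evalue",
    "bit_score", "identity", "coverage", "query_aligned", "target_aligned",
    "target_tax_id", "query_tax_id", "sifts_score", "pdb_cross_references",
    "adjusted_score", "tax_score", "dataset_score", "hit_rank",
)


def hit_row(scored: ScoredHit) -> list[str]:
    hit = scored.hit
    values = {
        "entry": hit.entry,
        "entity": hit.entity,
        "accession": hit.accession,
        "alignment_len": hit.alignment_len,
        "query_len": hit.query_len,
        "mismatch": hit.mismatch,
        "query_start": hit.query_start,
        "query_end": hit.query_end,
        "target_start": hit.target_start,
        "target_end": hit.target_end,
        "evalue": f"{hit.evalue:.3g}",
        "bit_score": f"{hit.bit_score:.2f}",
        "identity": f"{hit.identity:.6f}",
        "coverage": f"{hit.coverage:.6f}",
        "query_aligned": hit.query_aligned,
        "target_aligned": hit.target_aligned,
        "target_tax_id": hit.target_tax_id,
        "query_tax_id": hit.query_tax_id,
        "sifts_score": f"{scored.sifts_score:.4f}",
        "pdb_cross_references": scored.pdb_cross_references,
        "adjusted_score": f"{scored.adjusted_score:.4f}",
        "tax_score": scored.tax_score,
        "dataset_score": scored.dataset_score,
        "hit_rank": scored.hit_rank,
    }
    return [str(values[col]) for col in HITS_TSV_COLUMNS]


def write_hits_tsv(hits: Iterable[ScoredHit], path: str | os.PathLike) -> int:
    """Write scored hits as TSV in :data:`HITS_TSV_COLUMNS` order."""
    count = 0
    with open(path, "w") as fh:
        fh.write("\t".join(HITS_TSV_COLUMNS) + "\n")
        for scored in hits:
            fh.write("\t".join(hit_row(scored)) + "\n")
            count += 1
    return count
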