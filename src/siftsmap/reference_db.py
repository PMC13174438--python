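"""Indexed reference sequence sets and the built-in exhaustive search backend.

The on-disk index is a directory holding a single ``records.tsv`` with all
reference records and their taxonomy/provenance metadata.  The built-in
search backend aligns the query against every record with a local
Smith–Waterman (BLOSUM62, gap open 11 / extend 1) and applies the
sequence-identity cutoff (default 90%).  Tabular hit files produced by
external search tools are consumed through :func:`parse_search_tsv`.
"""
from __future__ import annotations

import math
import os
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO

from .align import AlignerParams, best_local_alignment
from .errors import (
    DuplicateAccessionError,
    InputError,
    MissingTaxonomyError,
    SiftsmapError,
)
from .residues import VALID_LETTERS

__all__ = [
    "ReferenceRecord",
    "RawHit",
    "SearchParams",
    "ReferenceDB",
    "build_reference_db",
    "search",
    "parse_search_tsv",
    "SEARCH_TSV_COLUMNS",
]

DATASETS = ("reviewed", "unreviewed", "other")

# gapped Karlin-Altschul constants for BLOSUM62 with gap open 11 / extend 1
_KA_LAMBDA = 0.267
_KA_K = 0.041


@dataclass
class ReferenceRecord:
    accession: str
    name: str
    seq_version: int
    sequence: str
    dataset: str  # reviewed | unreviewed | other
    tax_id: int
    annotation_score: int = 0
    pdb_xref_count: int = 0

    def __post_init__(self):
        if self.dataset not in DATASETS:
            raise InputError(f"unknown dataset {self.dataset!r}")
        if not self.sequence:
            raise InputError(f"{self.accession}: empty sequence")
        if not 0 <= self.annotation_score <= 5:
            raise InputError(
                f"{self.accession}: annotation score {self.annotation_score} "
                "outside 0..5"
            )


@dataclass
class RawHit:
    """One query/target alignment candidate before scoring."""

    entry: str
    entity: str
    accession: str
    alignment_len: int
    query_len: int
    mismatch: int
    query_start: int
    query_end: int
    target_start: int
    target_end: int
    evalue: float
    bit_score: float
    identity: float
    coverage: float
    query_aligned: str
    target_aligned: str
    query_tax_id: int
    target_tax_id: int
    filtered: bool = False  # set when the hit fails the identity cutoff

    def __post_init__(self):
        if len(self.query_aligned) != len(self.target_aligned):
            raise InputError("gapped alignment strings differ in length")
        if self.query_start > self.query_end or self.target_start > self.target_end:
            raise InputError("alignment coordinates are reversed")


@dataclass
class SearchParams:
    min_identity: float = 0.9
    gap_open: float = 11.0
    gap_extend: float = 1.0
    matrix_name: str = "BLOSUM62"
    gapless_prefilter: bool = False  # pass-through option for external backends

    def __post_init__(self):
        if not 0.0 <= self.min_identity <= 1.0:
            raise InputError("min_identity must lie in [0, 1]")


class ReferenceDB:
    """In-memory handle over an on-disk reference index."""

    RECORD_FIELDS = (
        "accession", "name", "seq_version", "dataset",
        "tax_id", "annotation_score", "pdb_xref_count", "sequence",
    )

    def __init__(self, records: dict[str, ReferenceRecord], location: Path | None = None):
        self.records = records
        self.location = location

    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, accession: str) -> bool:
        return accession in self.records

    def get(self, accession: str) -> ReferenceRecord | None:
        return self.records.get(accession)

    @property
    def total_residues(self) -> int:
        return sum(len(r.sequence) for r in self.records.values())

    @classmethod
    def open(cls, path: str | os.PathLike) -> "ReferenceDB":
        path = Path(path)
        index = path / "records.tsv"
        if not index.is_file():
            raise SiftsmapError(f"not a reference index: {index} missing")
        records: dict[str, ReferenceRecord] = {}
        with open(index) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            if tuple(header) != cls.RECORD_FIELDS:
                raise SiftsmapError(f"unexpected index header in {index}")
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                rec = ReferenceRecord(
                    accession=parts[0],
                    name=parts[1],
                    seq_version=int(parts[2]),
                    dataset=parts[3],
                    tax_id=int(parts[4]),
                    annotation_score=int(parts[5]),
                    pdb_xref_count=int(parts[6]),
                    sequence=parts[7],
                )
                records[rec.accession] = rec
        return cls(records, location=path)

    def save(self, path: str | os.PathLike) -> Path:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        index = path / "records.tsv"
        with open(index, "w") as fh:
            fh.write("\t".join(self.RECORD_FIELDS) + "\n")
            for acc in sorted(self.records):
                r = self.records[acc]
                fh.write(
                    "\t".join(
                        [
                            r.accession, r.name, str(r.seq_version), r.dataset,
                            str(r.tax_id), str(r.annotation_score),
                            str(r.pdb_xref_count), r.sequence,
                        ]
                    )
                    + "\n"
                )
        self.location = path
        return path


def _parse_header(description: str) -> tuple[str, str, str, int]:
    """FASTA header -> (accession, name, dataset, seq_version).

    Strict ``db|ACC|NAME`` with ``sp`` -> reviewed and ``tr`` -> unreviewed;
    any other shape falls back to the first whitespace token as accession
    with dataset ``other``.
    """
    token = description.split()[0]
    parts = token.split("|")
    seq_version = 1
    for word in description.split():
        if word.startswith("SV="):
            try:
                seq_version = int(word[3:])
            except ValueError:
                pass
    if len(parts) == 3 and parts[0] in ("sp", "tr") and parts[1]:
        dataset = "reviewed" if parts[0] == "sp" else "unreviewed"
        return parts[1], parts[2], dataset, seq_version
    return token, token, "other", seq_version


def _read_two_column_tsv(path: str | os.PathLike, what: str) -> dict[str, str]:
    table: dict[str, str] = {}
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise InputError(f"{what} line {line_no}: expected 2 columns")
            table[parts[0]] = parts[1]
    return table


def build_reference_db(
    fasta: str | os.PathLike,
    taxonomy_tsv: str | os.PathLike,
    annotation_tsv: str | os.PathLike | None = None,
    xref_tsv: str | os.PathLike | None = None,
    out: str | os.PathLike | None = None,
) -> ReferenceDB:
    """Build an indexed reference set from FASTA plus metadata tables.

    Every FASTA identifier must appear in the taxonomy TSV
    (``identifier<TAB>taxid``); annotation scores and PDB cross-reference
    counts default to 0 when their tables are absent.
    """
    taxonomy = _read_two_column_tsv(taxonomy_tsv, "taxonomy TSV")
    annotations = (
        _read_two_column_tsv(annotation_tsv, "annotation TSV")
        if annotation_tsv is not None
        else {}
    )
    xrefs = (
        _read_two_column_tsv(xref_tsv, "xref TSV") if xref_tsv is not None else {}
    )

    records: dict[str, ReferenceRecord] = {}
    for seq_record in SeqIO.parse(str(fasta), "fasta"):
        accession, name, dataset, seq_version = _parse_header(seq_record.description)
        if accession in records:
            raise DuplicateAccessionError(f"duplicate accession {accession!r}")
        if accession not in taxonomy:
            raise MissingTaxonomyError(accession)
        sequence = str(seq_record.seq).upper()
        records[accession] = ReferenceRecord(
            accession=accession,
            name=name,
            seq_version=seq_version,
            sequence=sequence,
            dataset=dataset,
            tax_id=int(taxonomy[accession]),
            annotation_score=int(annotations.get(accession, 0)),
            pdb_xref_count=int(xrefs.get(accession, 0)),
        )
    db = ReferenceDB(records)
    if out is not None:
        db.save(out)
    return db


def _hit_statistics(alignment, query_len: int, db_residues: int):
    cols = alignment.columns
    aligned_cols = [(q, t) for q, t in cols if q != "-" and t != "-"]
    identical = sum(1 for q, t in aligned_cols if q == t)
    mismatch = len(aligned_cols) - identical
    alignment_len = len(cols)
    identity = identical / alignment_len if alignment_len else 0.0
    coverage = len(aligned_cols) / query_len if query_len else 0.0
    bit_score = (_KA_LAMBDA * alignment.score - math.log(_KA_K)) / math.log(2)
    evalue = query_len * max(db_residues, 1) * 2.0 ** (-bit_score)
    return alignment_len, mismatch, identity, coverage, bit_score, evalue


def search(
    query: str,
    query_tax_id: int,
    db: ReferenceDB,
    params: SearchParams | None = None,
    entry: str = "",
    entity: str = "",
) -> list[RawHit]:
    """Exhaustively align *query* against every reference record.

    Hits below ``params.min_identity`` are discarded.  Ordering is
    deterministic: alignment score descending, then accession ascending.
    """
    params = params or SearchParams()
    if not query:
        raise InputError("query sequence is empty")
    bad = set(query.upper()) - VALID_LETTERS
    if bad:
        raise InputError(f"query has non-amino-acid letters: {sorted(bad)}")

    aligner_params = AlignerParams(
        matrix_name=params.matrix_name,
        gap_open=params.gap_open,
        gap_extend=params.gap_extend,
    )
    db_residues = db.total_residues
    scored: list[tuple[float, str, RawHit]] = []
    for accession in sorted(db.records):
        record = db.records[accession]
        alignment = best_local_alignment(query, record.sequence, aligner_params)
        if alignment is None:
            continue
        (alignment_len, mismatch, identity, coverage,
         bit_score, evalue) = _hit_statistics(alignment, len(query), db_residues)
        if identity < params.min_identity:
            continue
        hit = RawHit(
            entry=entry,
            entity=entity,
            accession=accession,
            alignment_len=alignment_len,
            query_len=len(query),
            mismatch=mismatch,
            query_start=alignment.query_start,
            query_end=alignment.query_end,
            target_start=alignment.target_start,
            target_end=alignment.target_end,
            evalue=evalue,
            bit_score=bit_score,
            identity=identity,
            coverage=coverage,
            query_aligned=alignment.query_aligned,
            target_aligned=alignment.target_aligned,
            query_tax_id=query_tax_id,
            target_tax_id=record.tax_id,
        )
        scored.append((alignment.score, accession, hit))
    scored.sort(key=lambda item: (-item[0], item[1]))
    return [hit for _, _, hit in scored]


#: fixed column order of the external search-hit TSV adapter
SEARCH_TSV_COLUMNS = (
    "entry", "entity", "accession", "alignment_len", "query_len", "mismatch",
    "query_start", "query_end", "target_start", "target_end", "evalue",
    "bit_score", "identity", "coverage", "query_aligned", "target_aligned",
    "query_tax_id",
)


def parse_search_tsv(
    path: str | os.PathLike,
    db: ReferenceDB,
    params: SearchParams | None = None,
) -> list[RawHit]:
    """Read hits from an external search tool's tabular output.

    Columns must follow :data:`SEARCH_TSV_COLUMNS` (no header).  Target
    taxids are joined from the reference index.  Rows failing the identity
    cutoff are returned with ``filtered=True`` rather than dropped.
    """
    params = params or SearchParams()
    hits: list[RawHit] = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != len(SEARCH_TSV_COLUMNS):
                raise InputError(
                    f"{path} line {line_no}: expected "
                    f"{len(SEARCH_TSV_COLUMNS)} columns, found {len(parts)}"
                )
            row = dict(zip(SEARCH_TSV_COLUMNS, parts))
            record = db.get(row["accession"])
            if record is None:
                raise SiftsmapError(
                    f"{path} line {line_no}: accession "
                    f"{row['accession']!r} not in reference index"
                )
            identity = float(row["identity"])
            hit = RawHit(
                entry=row["entry"],
                entity=row["entity"],
                accession=row["accession"],
                alignment_len=int(row["alignment_len"]),
                query_len=int(row["query_len"]),
                mismatch=int(row["mismatch"]),
                query_start=int(row["query_start"]),
                query_end=int(row["query_end"]),
                target_start=int(row["target_start"]),
                target_end=int(row["target_end"]),
                evalue=float(row["evalue"]),
                bit_score=float(row["bit_score"]),
                identity=identity,
                coverage=float(row["coverage"]),
                query_aligned=row["query_aligned"],
                target_aligned=row["target_aligned"],
                query_tax_id=int(row["query_tax_id"]),
                target_tax_id=record.tax_id,
                filtered=identity < params.min_identity,
            )
            hits.append(hit)
    return hits
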