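"""Persistence: per-entry gzip CSV outputs and a single-file embedded
analytical database holding the three mapping tables (hits,
sifts_xref_segment, sifts_xref_residue).

Hits live only in the database; segment- and residue-level rows are
written per entry as gzip-compressed CSV (RFC 4180, UTF-8, header row,
lowercase true/false booleans, empty string for null) and bulk-loaded
transactionally by :func:`db_load`.  Reloading an entry replaces its rows.
"""
from __future__ import annotations

import csv
import gzip
import os
import sqlite3
from dataclasses import asdict, dataclass, field
from pathlib import Path

from .scoring import HITS_TSV_COLUMNS, ScoredHit, hit_row
from .segmenter import ResidueXref, Segment

__all__ = [
    "MappingStore",
    "LoadReport",
    "write_entry_outputs",
    "read_entry_outputs",
    "db_load",
    "SEGMENT_COLUMNS",
    "RESIDUE_COLUMNS",
]

SEGMENT_COLUMNS = (
    "entry", "entity", "auth_asym_id", "struct_asym_id", "accession", "name",
    "seq_version", "query_start", "query_end", "target_start", "target_end",
    "auth_start", "auth_end", "auth_code", "target_alignment",
    "query_alignment", "identity", "score", "conflicts", "modifications",
    "best_mapping", "canonical_acc", "chimera", "tax_id",
)

RESIDUE_COLUMNS = (
    "entry", "entity", "auth_asym_id", "struct_asym_id", "target_segment_id",
    "auth_seq_id", "auth_seq_id_ins_code", "query_seq_id", "target_seq_id",
    "observed", "query_one_letter_code", "target_one_letter_code",
    "chem_comp_id", "type", "tax_id", "best_mapping", "canonical_acc",
    "residue_id", "accession",
)

SEGMENT_FILE = "sifts_xref_segment.csv.gz"
RESIDUE_FILE = "sifts_xref_residue.csv.gz"

_BOOL_FIELDS = {"best_mapping", "canonical_acc", "chimera", "observed"}


def _cell(value) -> str:
    if value is None:
        return ""
    if isinstance(value, bool):
        return "true" if value else "false"
    return str(value)


def _row(obj, columns) -> list[str]:
    data = asdict(obj)
    return [_cell(data[col]) for col in columns]


def write_entry_outputs(
    entry_dir: str | os.PathLike,
    segments: list[Segment],
    residues: list[ResidueXref],
) -> tuple[Path, Path]:
    """Write an entry's segment and residue CSVs (gzip, atomic rename)."""
    entry_dir = Path(entry_dir)
    entry_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for filename, columns, rows in (
        (SEGMENT_FILE, SEGMENT_COLUMNS, segments),
        (RESIDUE_FILE, RESIDUE_COLUMNS, residues),
    ):
        final = entry_dir / filename
        tmp = entry_dir / (filename + ".tmp")
        try:
            with gzip.open(tmp, "wt", newline="") as fh:
                writer = csv.writer(fh)
                writer.writerow(columns)
                for obj in rows:
                    writer.writerow(_row(obj, columns))
            os.replace(tmp, final)
        except BaseException:
            tmp.unlink(missing_ok=True)
            raise
        paths.append(final)
    return paths[0], paths[1]


def _parse_bool(value: str) -> bool:
    return value.strip().lower() == "true"


def read_entry_outputs(
    entry_dir: str | os.PathLike,
) -> tuple[list[Segment], list[ResidueXref]]:
    """Read an entry's CSVs back into Segment / ResidueXref rows."""
    entry_dir = Path(entry_dir)
    segments: list[Segment] = []
    residues: list[ResidueXref] = []
    with gzip.open(entry_dir / SEGMENT_FILE, "rt", newline="") as fh:
        for row in csv.DictReader(fh):
            segments.append(
                Segment(
                    entry=row["entry"], entity=row["entity"],
                    auth_asym_id=row["auth_asym_id"],
                    struct_asym_id=row["struct_asym_id"],
                    accession=row["accession"], name=row["name"],
                    seq_version=int(row["seq_version"]),
                    query_start=int(row["query_start"]),
                    query_end=int(row["query_end"]),
                    target_start=int(row["target_start"]),
                    target_end=int(row["target_end"]),
                    auth_start=int(row["auth_start"]),
                    auth_end=int(row["auth_end"]),
                    auth_code=row["auth_code"],
                    target_alignment=row["target_alignment"],
                    query_alignment=row["query_alignment"],
                    identity=float(row["identity"]),
                    score=float(row["score"]),
                    conflicts=int(row["conflicts"]),
                    modifications=int(row["modifications"]),
                    best_mapping=_parse_bool(row["best_mapping"]),
                    canonical_acc=_parse_bool(row["canonical_acc"]),
                    chimera=_parse_bool(row["chimera"]),
                    tax_id=int(row["tax_id"]),
                )
            )
    with gzip.open(entry_dir / RESIDUE_FILE, "rt", newline="") as fh:
        for row in csv.DictReader(fh):
            residues.append(
                ResidueXref(
                    entry=row["entry"], entity=row["entity"],
                    auth_asym_id=row["auth_asym_id"],
                    struct_asym_id=row["struct_asym_id"],
                    target_segment_id=int(row["target_segment_id"]),
                    auth_seq_id=int(row["auth_seq_id"]),
                    auth_seq_id_ins_code=row["auth_seq_id_ins_code"],
                    query_seq_id=int(row["query_seq_id"]),
                    target_seq_id=int(row["target_seq_id"]),
                    observed=_parse_bool(row["observed"]),
                    query_one_letter_code=row["query_one_letter_code"],
                    target_one_letter_code=row["target_one_letter_code"],
                    chem_comp_id=row["chem_comp_id"],
                    type=row["type"],
                    tax_id=int(row["tax_id"]),
                    best_mapping=_parse_bool(row["best_mapping"]),
                    canonical_acc=_parse_bool(row["canonical_acc"]),
                    residue_id=int(row["residue_id"]),
                    accession=row["accession"],
                )
            )
    return segments, residues


class MappingStore:
    """Single-file embedded database with the three mapping tables."""

    def __init__(self, location: str | os.PathLike):
        self.location = Path(location)
        self._conn = sqlite3.connect(self.location)
        self._create_tables()

    def close(self) -> None:
        self._conn.close()

    def __enter__(self) -> "MappingStore":
        return self

    def __exit__(self, *exc) -> None:
        self.close()

    def _create_tables(self) -> None:
        cur = self._conn.cursor()
        hits_cols = ", ".join(f'"{c}"' for c in HITS_TSV_COLUMNS)
        cur.execute(f"CREATE TABLE IF NOT EXISTS hits ({hits_cols})")
        cur.execute(
            "CREATE UNIQUE INDEX IF NOT EXISTS hits_key "
            "ON hits (entry, entity, accession, hit_rank)"
        )
        seg_cols = ", ".join(f'"{c}"' for c in SEGMENT_COLUMNS)
        cur.execute(f"CREATE TABLE IF NOT EXISTS sifts_xref_segment ({seg_cols})")
        res_cols = ", ".join(f'"{c}"' for c in RESIDUE_COLUMNS)
        cur.execute(f"CREATE TABLE IF NOT EXISTS sifts_xref_residue ({res_cols})")
        cur.execute(
            "CREATE UNIQUE INDEX IF NOT EXISTS residue_key "
            "ON sifts_xref_residue "
            "(entry, entity, auth_asym_id, residue_id, accession)"
        )
        cur.execute(
            "CREATE INDEX IF NOT EXISTS residue_best "
            "ON sifts_xref_residue (entry, entity, best_mapping)"
        )
        self._conn.commit()

    def count(self, table: str) -> int:
        if table not in ("hits", "sifts_xref_segment", "sifts_xref_residue"):
            raise ValueError(f"unknown table {table!r}")
        (n,) = self._conn.execute(f"SELECT COUNT(*) FROM {table}").fetchone()
        return n

    def load_hits(self, hits: list[ScoredHit]) -> int:
        placeholders = ",".join("?" * len(HITS_TSV_COLUMNS))
        rows = [hit_row(h) for h in hits]
        with self._conn:
            self._conn.executemany(f"INSERT INTO hits VALUES ({placeholders})", rows)
        return len(rows)

    def best_mapping(self, entry: str, entity: str) -> list[tuple]:
        """All best-mapping residue rows for one entry/entity (single scan)."""
        return self._conn.execute(
            "SELECT * FROM sifts_xref_residue "
            "WHERE entry = ? AND entity = ? AND best_mapping = 'true'",
            (entry, entity),
        ).fetchall()


@dataclass
class LoadReport:
    entries_scanned: int = 0
    files_loaded: int = 0
    segment_rows_appended: int = 0
    residue_rows_appended: int = 0
    rejects: list[tuple[str, str]] = field(default_factory=list)  # (path, reason)


def _validate_csv(path: Path, columns) -> list[list[str]] | str:
    """Rows on success, reason string on failure."""
    try:
        with gzip.open(path, "rt", newline="") as fh:
            reader = csv.reader(fh)
            header = next(reader, None)
            if header is None:
                return "empty file (missing header)"
            if tuple(header) != tuple(columns):
                return "schema mismatch: unexpected header"
            rows = []
            for i, row in enumerate(reader, start=2):
                if len(row) != len(columns):
                    return f"schema mismatch: wrong column count at line {i}"
                rows.append(row)
            return rows
    except (OSError, EOFError, gzip.BadGzipFile) as exc:
        return f"unreadable: {exc}"


def db_load(root: str | os.PathLike, store: MappingStore) -> LoadReport:
    """Scan a root output directory and bulk-load all valid entry files.

    All valid files are appended in one transaction: either every valid
    file's rows land or none do.  Invalid files are reported, never
    partially loaded.  Entries already present are replaced.
    """
    root = Path(root)
    if not root.is_dir():
        raise FileNotFoundError(f"root directory {root} does not exist")
    report = LoadReport()

    loads: list[tuple[str, list[list[str]], list[list[str]]]] = []
    for entry_dir in sorted(p for p in root.iterdir() if p.is_dir()):
        seg_path = entry_dir / SEGMENT_FILE
        res_path = entry_dir / RESIDUE_FILE
        if not seg_path.is_file() and not res_path.is_file():
            continue
        report.entries_scanned += 1
        if not seg_path.is_file() or not res_path.is_file():
            report.rejects.append((str(entry_dir), "incomplete entry outputs"))
            continue
        seg_rows = _validate_csv(seg_path, SEGMENT_COLUMNS)
        if isinstance(seg_rows, str):
            report.rejects.append((str(seg_path), seg_rows))
            continue
        res_rows = _validate_csv(res_path, RESIDUE_COLUMNS)
        if isinstance(res_rows, str):
            report.rejects.append((str(res_path), res_rows))
            continue
        loads.append((entry_dir.name, seg_rows, res_rows))

    conn = store._conn
    seg_before = store.count("sifts_xref_segment")
    res_before = store.count("sifts_xref_residue")
    seg_ph = ",".join("?" * len(SEGMENT_COLUMNS))
    res_ph = ",".join("?" * len(RESIDUE_COLUMNS))
    with conn:
        for entry_name, seg_rows, res_rows in loads:
            entries = {row[0] for row in seg_rows} | {row[0] for row in res_rows}
            for entry_id in entries or {entry_name}:
                conn.execute(
                    "DELETE FROM sifts_xref_segment WHERE entry = ?", (entry_id,)
                )
                conn.execute(
                    "DELETE FROM sifts_xref_residue WHERE entry = ?", (entry_id,)
                )
            conn.executemany(
                f"INSERT INTO sifts_xref_segment VALUES ({seg_ph})", seg_rows
            )
            conn.executemany(
                f"INSERT INTO sifts_xref_residue VALUES ({res_ph})", res_rows
            )
            report.files_loaded += 1
    report.segment_rows_appended = store.count("sifts_xref_segment") - seg_before
    report.residue_rows_appended = store.count("sifts_xref_residue") - res_before
    return report
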