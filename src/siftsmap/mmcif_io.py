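"""PDBx/mmCIF input/output.

Reads polymer entities (sample sequences, numbering schemes, observation
flags and backbone coordinates) and writes cross-reference annotation
categories back into mmCIF.

The annotation writer populates ``_pdbx_sifts_unp_segments`` and
``_pdbx_sifts_xref_db`` and extends ``atom_site`` with the
``pdbx_sifts_xref_db_name`` / ``_acc`` / ``_num`` / ``_res`` items of the
current PDBx/mmCIF dictionary, so each atom row of a mapped residue
carries the reference accession and reference residue number of the best
mapping.
"""
from __future__ import annotations

import gzip
import io
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from biotite.structure.io.pdbx import CIFCategory, CIFFile

from .ccd import ComponentDictionary, backbone_atom_names
from .errors import (
    ConsistencyError,
    MmcifParseError,
    NoPolymerEntityError,
    WriteError,
)
from .residues import ONE_TO_THREE, THREE_TO_ONE, VALID_LETTERS

__all__ = [
    "ResidueRecord",
    "ChainInstance",
    "PolymerEntity",
    "parse_polymer_entities",
    "write_fasta",
    "write_sifts_annotations",
]


@dataclass
class ResidueRecord:
    """One position of a chain's sample sequence.

    ``observed`` is true iff at least one atom of the residue is present in
    the coordinate record; unobserved residues keep their place in the
    sequence but carry no coordinates.
    """

    label_seq_id: int
    auth_seq_id: int
    ins_code: str
    chem_comp_id: str
    one_letter: str
    observed: bool
    n_coord: np.ndarray | None = None
    c_coord: np.ndarray | None = None

    def __post_init__(self):
        if not self.observed and (self.n_coord is not None or self.c_coord is not None):
            raise ConsistencyError(
                f"unobserved residue {self.label_seq_id} carries coordinates"
            )
        if self.one_letter not in VALID_LETTERS:
            raise ConsistencyError(
                f"residue {self.label_seq_id}: invalid one-letter code "
                f"{self.one_letter!r}"
            )


@dataclass
class ChainInstance:
    auth_asym_id: str
    struct_asym_id: str
    residues: list[ResidueRecord] = field(default_factory=list)

    def residue_by_label(self, label_seq_id: int) -> ResidueRecord:
        return self.residues[label_seq_id - 1]


@dataclass
class PolymerEntity:
    entry_id: str
    entity_id: str
    sample_sequence: str
    chains: list[ChainInstance] = field(default_factory=list)

    def validate(self) -> None:
        if not self.sample_sequence:
            raise ConsistencyError(f"entity {self.entity_id}: empty sample sequence")
        bad = set(self.sample_sequence) - VALID_LETTERS
        if bad:
            raise ConsistencyError(
                f"entity {self.entity_id}: invalid sequence letters {sorted(bad)}"
            )
        for chain in self.chains:
            if len(chain.residues) != len(self.sample_sequence):
                raise ConsistencyError(
                    f"entity {self.entity_id} chain {chain.struct_asym_id}: "
                    f"{len(chain.residues)} residues for a "
                    f"{len(self.sample_sequence)}-residue sample sequence"
                )


# ---------------------------------------------------------------------------
# reading


def _read_text(source: str | os.PathLike) -> str:
    """Accept a filesystem path or raw mmCIF text; gzip by magic bytes."""
    if isinstance(source, str) and "\n" in source:
        return source
    with open(source, "rb") as fh:
        data = fh.read()
    if data[:2] == b"\x1f\x8b":
        data = gzip.decompress(data)
    return data.decode()


def _load_block(text: str):
    try:
        cif = CIFFile.read(io.StringIO(text))
    except Exception as exc:  # biotite raises several syntax error types
        raise MmcifParseError(f"cannot parse mmCIF: {exc}") from exc
    names = list(cif.keys())
    if not names:
        raise MmcifParseError("mmCIF contains no data block")
    return cif, cif[names[0]], names[0]


def _column(category, item, n=None):
    arr = category[item].as_array(str)
    if n is not None and len(arr) != n:
        raise MmcifParseError("ragged loop", category=category.name)
    return [str(v) for v in arr]


def parse_polymer_entities(
    mmcif_source: str | os.PathLike,
    ccd: ComponentDictionary | None = None,
) -> list[PolymerEntity]:
    """Extract all polypeptide entities from an mmCIF file or text.

    Unobserved residues remain in the residue list with ``observed=False``.
    When ``_pdbx_poly_seq_scheme`` is absent the per-chain records are
    synthesised from the sample sequence with author numbering equal to
    label numbering.  Coordinates are taken from the first model only.
    """
    text = _read_text(mmcif_source)
    _, block, block_name = _load_block(text)

    if "entry" in block and "id" in block["entry"]:
        entry_id = str(block["entry"]["id"].as_item()).lower()
    else:
        entry_id = block_name.lower()

    if "entity_poly" not in block:
        raise NoPolymerEntityError(
            f"{entry_id}: no _entity_poly category; file has no polymer entity"
        )
    poly = block["entity_poly"]
    try:
        entity_ids = _column(poly, "entity_id")
        types = _column(poly, "type", n=len(entity_ids))
        seqs = _column(poly, "pdbx_seq_one_letter_code_can", n=len(entity_ids))
    except KeyError as exc:
        raise MmcifParseError(f"missing item {exc}", category="entity_poly") from exc

    strand_ids = (
        _column(poly, "pdbx_strand_id", n=len(entity_ids))
        if "pdbx_strand_id" in poly
        else [""] * len(entity_ids)
    )

    polypeptides: dict[str, str] = {}
    strands: dict[str, list[str]] = {}
    for eid, etype, seq, strand in zip(entity_ids, types, seqs, strand_ids):
        if not etype.lower().startswith("polypeptide"):
            continue
        seq = "".join(seq.split()).upper()
        if not seq:
            raise MmcifParseError(
                f"entity {eid}: empty sample sequence", category="entity_poly"
            )
        seq = "".join(c if c in VALID_LETTERS else "X" for c in seq)
        polypeptides[eid] = seq
        strands[eid] = [s.strip() for s in strand.split(",") if s.strip()]

    if not polypeptides:
        raise NoPolymerEntityError(f"{entry_id}: no polypeptide entity present")

    atom_index = _index_atom_sites(block)
    scheme = _read_scheme(block) if "pdbx_poly_seq_scheme" in block else None

    entities = []
    for eid, seq in polypeptides.items():
        entity = PolymerEntity(entry_id=entry_id, entity_id=eid, sample_sequence=seq)
        if scheme is not None and eid in scheme:
            for asym_id, rows in scheme[eid].items():
                entity.chains.append(
                    _chain_from_scheme(asym_id, rows, seq, atom_index, ccd)
                )
        else:
            for strand in strands[eid] or [f"A{eid}"]:
                entity.chains.append(
                    _chain_synthesised(strand, seq, atom_index, ccd)
                )
        entity.validate()
        entities.append(entity)
    return entities


def _index_atom_sites(block) -> dict[tuple[str, int], dict[str, np.ndarray]]:
    """(label_asym_id, label_seq_id) -> {atom_name: xyz}, first model only."""
    if "atom_site" not in block:
        return {}
    cat = block["atom_site"]
    try:
        asym = _column(cat, "label_asym_id")
        n = len(asym)
        seq = _column(cat, "label_seq_id", n=n)
        names = _column(cat, "label_atom_id", n=n)
        xs = _column(cat, "Cartn_x", n=n)
        ys = _column(cat, "Cartn_y", n=n)
        zs = _column(cat, "Cartn_z", n=n)
    except KeyError as exc:
        raise MmcifParseError(f"missing item {exc}", category="atom_site") from exc
    models = (
        _column(cat, "pdbx_PDB_model_num", n=n)
        if "pdbx_PDB_model_num" in cat
        else ["1"] * n
    )
    first_model = models[0]
    index: dict[tuple[str, int], dict[str, np.ndarray]] = {}
    for i in range(n):
        if models[i] != first_model:
            continue
        if seq[i] in (".", "?", ""):
            continue  # non-polymer atom
        try:
            key = (asym[i], int(seq[i]))
            coord = np.array([float(xs[i]), float(ys[i]), float(zs[i])])
        except ValueError as exc:
            raise MmcifParseError(
                f"non-numeric value in row {i + 1}: {exc}", category="atom_site"
            ) from exc
        index.setdefault(key, {})[names[i]] = coord
    return index


def _read_scheme(block) -> dict[str, dict[str, list[dict]]]:
    """entity_id -> struct_asym_id -> ordered residue rows."""
    cat = block["pdbx_poly_seq_scheme"]
    try:
        asym = _column(cat, "asym_id")
        n = len(asym)
        entity = _column(cat, "entity_id", n=n)
        seq_id = _column(cat, "seq_id", n=n)
        mon = _column(cat, "mon_id", n=n)
    except KeyError as exc:
        raise MmcifParseError(
            f"missing item {exc}", category="pdbx_poly_seq_scheme"
        ) from exc
    auth_num = (
        _column(cat, "pdb_seq_num", n=n) if "pdb_seq_num" in cat else seq_id
    )
    strand = (
        _column(cat, "pdb_strand_id", n=n) if "pdb_strand_id" in cat else asym
    )
    ins = (
        _column(cat, "pdb_ins_code", n=n)
        if "pdb_ins_code" in cat
        else ["."] * n
    )
    out: dict[str, dict[str, list[dict]]] = {}
    for i in range(n):
        try:
            label = int(seq_id[i])
        except ValueError as exc:
            raise MmcifParseError(
                f"non-integer seq_id {seq_id[i]!r}", category="pdbx_poly_seq_scheme"
            ) from exc
        row = {
            "label_seq_id": label,
            "auth_seq_id": auth_num[i],
            "ins_code": "" if ins[i] in (".", "?") else ins[i],
            "mon_id": mon[i],
            "auth_asym_id": strand[i],
        }
        out.setdefault(entity[i], {}).setdefault(asym[i], []).append(row)
    return out


def _one_letter(mon_id: str, ccd: ComponentDictionary | None) -> str:
    if ccd is not None:
        return ccd.one_letter(mon_id)
    return THREE_TO_ONE.get(mon_id.upper(), "X")


def _make_residue(
    label_seq_id: int,
    auth_seq_id: int,
    ins_code: str,
    mon_id: str,
    struct_asym_id: str,
    atom_index,
    ccd,
) -> ResidueRecord:
    atoms = atom_index.get((struct_asym_id, label_seq_id))
    observed = atoms is not None and len(atoms) > 0
    n_coord = c_coord = None
    if observed:
        n_name, c_name = backbone_atom_names(mon_id, ccd)
        n_coord = atoms.get(n_name)
        c_coord = atoms.get(c_name)
    return ResidueRecord(
        label_seq_id=label_seq_id,
        auth_seq_id=auth_seq_id,
        ins_code=ins_code,
        chem_comp_id=mon_id.upper(),
        one_letter=_one_letter(mon_id, ccd),
        observed=observed,
        n_coord=n_coord,
        c_coord=c_coord,
    )


def _chain_from_scheme(asym_id, rows, sequence, atom_index, ccd) -> ChainInstance:
    rows = sorted(rows, key=lambda r: r["label_seq_id"])
    labels = [r["label_seq_id"] for r in rows]
    if labels != list(range(1, len(rows) + 1)):
        raise MmcifParseError(
            f"chain {asym_id}: seq_id not a 1-based gapless run",
            category="pdbx_poly_seq_scheme",
        )
    if len(rows) != len(sequence):
        raise MmcifParseError(
            f"chain {asym_id}: {len(rows)} scheme rows for a "
            f"{len(sequence)}-residue sample sequence",
            category="pdbx_poly_seq_scheme",
        )
    residues = []
    for row in rows:
        try:
            auth = int(row["auth_seq_id"])
        except ValueError:
            auth = row["label_seq_id"]
        residues.append(
            _make_residue(
                row["label_seq_id"], auth, row["ins_code"], row["mon_id"],
                asym_id, atom_index, ccd,
            )
        )
    return ChainInstance(
        auth_asym_id=rows[0]["auth_asym_id"],
        struct_asym_id=asym_id,
        residues=residues,
    )


def _chain_synthesised(strand, sequence, atom_index, ccd) -> ChainInstance:
    # auth numbering defaults to label numbering, empty insertion codes
    residues = []
    for i, letter in enumerate(sequence, start=1):
        mon = ONE_TO_THREE.get(letter, "UNK")
        residues.append(
            _make_residue(i, i, "", mon, strand, atom_index, ccd)
        )
    return ChainInstance(auth_asym_id=strand, struct_asym_id=strand, residues=residues)


# ---------------------------------------------------------------------------
# writing


def write_fasta(entities: Sequence[PolymerEntity], out: str | os.PathLike) -> int:
    """Write one FASTA record per entity (header ``>pdb|<entry>|<entity>``)."""
    if not entities:
        raise ValueError("no entities to write")
    out = Path(out)
    with open(out, "w") as fh:
        for entity in entities:
            fh.write(f">pdb|{entity.entry_id}|{entity.entity_id}\n")
            seq = entity.sample_sequence
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")
    return len(entities)


def _bool(flag: bool) -> str:
    return "y" if flag else "n"


def write_sifts_annotations(
    mmcif_source: str | os.PathLike,
    segments,
    residues,
    out: str | os.PathLike,
) -> Path:
    """Write the source mmCIF with cross-reference annotation categories added.

    ``segments`` / ``residues`` are :class:`siftsmap.segmenter.Segment` and
    :class:`siftsmap.segmenter.ResidueXref` rows for this entry.  Atom rows
    of residues in the best mapping gain the reference accession/number.
    """
    if not segments or not residues:
        raise ValueError("nothing to annotate: segments and residues are required")

    text = _read_text(mmcif_source)
    cif, block, _ = _load_block(text)
    entities = parse_polymer_entities(text)
    known_entities = {e.entity_id for e in entities}
    for seg in segments:
        if str(seg.entity) not in known_entities:
            raise ConsistencyError(
                f"segment references unknown entity {seg.entity!r}"
            )
    for res in residues:
        if str(res.entity) not in known_entities:
            raise ConsistencyError(
                f"residue row references unknown entity {res.entity!r}"
            )

    seg_cat = {
        "entity_id": [str(s.entity) for s in segments],
        "asym_id": [s.struct_asym_id for s in segments],
        "auth_asym_id": [s.auth_asym_id for s in segments],
        "unp_acc": [s.accession for s in segments],
        "segment_id": [str(i) for i in range(1, len(segments) + 1)],
        "instance_id": ["1"] * len(segments),
        "unp_start": [str(s.target_start) for s in segments],
        "unp_end": [str(s.target_end) for s in segments],
        "seq_id_start": [str(s.query_start) for s in segments],
        "seq_id_end": [str(s.query_end) for s in segments],
        "best_mapping": [_bool(s.best_mapping) for s in segments],
        "identity": [f"{s.identity:.3f}" for s in segments],
    }
    block["pdbx_sifts_unp_segments"] = CIFCategory(seg_cat)

    res_cat = {
        "entity_id": [str(r.entity) for r in residues],
        "asym_id": [r.struct_asym_id for r in residues],
        "auth_asym_id": [r.auth_asym_id for r in residues],
        "seq_id": [str(r.query_seq_id) for r in residues],
        "auth_seq_id": [str(r.auth_seq_id) for r in residues],
        "auth_ins_code": [r.auth_seq_id_ins_code or "?" for r in residues],
        "mon_id": [r.chem_comp_id for r in residues],
        "one_letter_code": [r.query_one_letter_code for r in residues],
        "observed": [_bool(r.observed) for r in residues],
        "unp_acc": [r.accession for r in residues],
        "unp_num": [str(r.target_seq_id) for r in residues],
        "unp_res": [r.target_one_letter_code for r in residues],
        "unp_segment_id": [str(r.target_segment_id) for r in residues],
        "best_mapping": [_bool(r.best_mapping) for r in residues],
    }
    block["pdbx_sifts_xref_db"] = CIFCategory(res_cat)

    _extend_atom_site(block, residues)

    out = Path(out)
    buffer = io.StringIO()
    cif.write(buffer)
    annotated = buffer.getvalue()
    try:
        reparsed = parse_polymer_entities(annotated)
    except Exception as exc:
        raise WriteError(f"annotated mmCIF failed to re-parse: {exc}") from exc
    if len(reparsed) != len(entities):
        raise WriteError("annotated mmCIF lost polymer entities")
    out.write_text(annotated)
    return out


def _extend_atom_site(block, residues) -> None:
    if "atom_site" not in block:
        return
    cat = block["atom_site"]
    columns = {name: cat[name].as_array(str) for name in cat.keys()}
    n = len(next(iter(columns.values())))
    best = {
        (r.struct_asym_id, int(r.query_seq_id)): r
        for r in residues
        if r.best_mapping
    }
    db_name, db_acc, db_num, db_res = [], [], [], []
    asym = columns.get("label_asym_id", ["?"] * n)
    seq = columns.get("label_seq_id", ["?"] * n)
    for i in range(n):
        key = None
        if str(seq[i]) not in (".", "?", ""):
            key = (str(asym[i]), int(seq[i]))
        row = best.get(key) if key else None
        if row is None:
            db_name.append("?")
            db_acc.append("?")
            db_num.append("?")
            db_res.append("?")
        else:
            db_name.append("UNP")
            db_acc.append(row.accession)
            db_num.append(str(row.target_seq_id))
            db_res.append(row.target_one_letter_code)
    columns["pdbx_sifts_xref_db_name"] = db_name
    columns["pdbx_sifts_xref_db_acc"] = db_acc
    columns["pdbx_sifts_xref_db_num"] = db_num
    columns["pdbx_sifts_xref_db_res"] = db_res
    block["atom_site"] = CIFCategory(columns)
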