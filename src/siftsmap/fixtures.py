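"""Deterministic synthetic inputs: toy mmCIF structures, reference sequence
sets with controlled identity/taxonomy, and an alignment-artefact case with
a known ground-truth refinement.

Coordinates are idealised extended-chain geometry: only consecutive C–N
distances matter to the pipeline (1.33 Å by default, overridden at declared
chain breaks).  All generators are pure functions of their spec + seed.
"""
from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path

from .align import AlignerParams, local_alignments
from .errors import FixtureError
from .mmcif_io import parse_polymer_entities
from .residues import ONE_TO_THREE, STANDARD_AA
from .segmenter import ISOLATED, RefinementParams, classify_runs, refine_alignment

__all__ = [
    "StructureSpec",
    "make_toy_structure",
    "ReferenceSetFixture",
    "make_reference_set",
    "IsolatedArtifactCase",
    "make_isolated_artifact_case",
    "toy_lineage_rows",
    "lineage_text",
    "make_toy_ccd",
]

PEPTIDE_BOND = 1.33  # Å, typical C-N peptide bond length


@dataclass
class StructureSpec:
    """Declarative description of a synthetic single-chain structure."""

    sequence: str
    entry_id: str = "toy1"
    entity_id: str = "1"
    chain_id: str = "A"
    auth_chain_id: str | None = None
    observed: list[bool] | None = None      # default: all observed
    auth_offset: int = 0                    # auth_seq_id = label_seq_id + offset
    breaks: list[tuple[int, float]] = field(default_factory=list)
    modified: dict[int, str] = field(default_factory=dict)  # position -> comp id
    seed: int = 0

    def __post_init__(self):
        if not self.sequence:
            raise FixtureError("sequence must be non-empty")
        n = len(self.sequence)
        if self.observed is not None and len(self.observed) != n:
            raise FixtureError("observed mask length must equal sequence length")
        for pos, _ in self.breaks:
            if not 1 <= pos < n:
                raise FixtureError(f"break position {pos} outside 1..{n - 1}")
        for pos in self.modified:
            if not 1 <= pos <= n:
                raise FixtureError(f"modified position {pos} outside sequence")


def make_toy_structure(spec: StructureSpec) -> str:
    """Render a spec as mmCIF text.

    Residue i places N, CA, C on the x axis; the C(i)–N(i+1) distance is
    1.33 Å except at declared breaks.  Unobserved residues appear in the
    sequence categories but have no atom rows.
    """
    n = len(spec.sequence)
    observed = spec.observed or [True] * n
    breaks = dict(spec.breaks)
    auth_chain = spec.auth_chain_id or spec.chain_id

    comp_ids = []
    for i, letter in enumerate(spec.sequence, start=1):
        comp_ids.append(spec.modified.get(i, ONE_TO_THREE.get(letter, "UNK")))

    lines = [f"data_{spec.entry_id}", "#", f"_entry.id   {spec.entry_id.upper()}", "#"]
    lines += [
        "loop_",
        "_entity_poly.entity_id",
        "_entity_poly.type",
        "_entity_poly.pdbx_seq_one_letter_code_can",
        "_entity_poly.pdbx_strand_id",
        f"{spec.entity_id} 'polypeptide(L)' {spec.sequence} {auth_chain}",
        "#",
    ]
    lines += [
        "loop_",
        "_pdbx_poly_seq_scheme.asym_id",
        "_pdbx_poly_seq_scheme.entity_id",
        "_pdbx_poly_seq_scheme.seq_id",
        "_pdbx_poly_seq_scheme.mon_id",
        "_pdbx_poly_seq_scheme.pdb_seq_num",
        "_pdbx_poly_seq_scheme.pdb_strand_id",
        "_pdbx_poly_seq_scheme.pdb_ins_code",
    ]
    for i in range(1, n + 1):
        lines.append(
            f"{spec.chain_id} {spec.entity_id} {i} {comp_ids[i - 1]} "
            f"{i + spec.auth_offset} {auth_chain} ."
        )
    lines.append("#")

    lines += [
        "loop_",
        "_atom_site.group_PDB",
        "_atom_site.id",
        "_atom_site.type_symbol",
        "_atom_site.label_atom_id",
        "_atom_site.label_comp_id",
        "_atom_site.label_asym_id",
        "_atom_site.label_entity_id",
        "_atom_site.label_seq_id",
        "_atom_site.Cartn_x",
        "_atom_site.Cartn_y",
        "_atom_site.Cartn_z",
        "_atom_site.auth_seq_id",
        "_atom_site.auth_asym_id",
        "_atom_site.pdbx_PDB_model_num",
    ]
    atom_id = 0
    x = 0.0
    for i in range(1, n + 1):
        coords = {"N": x, "CA": x + 0.75, "C": x + 1.50}
        if observed[i - 1]:
            for atom_name, atom_x in coords.items():
                atom_id += 1
                element = atom_name[0]
                lines.append(
                    f"ATOM {atom_id} {element} {atom_name} {comp_ids[i - 1]} "
                    f"{spec.chain_id} {spec.entity_id} {i} "
                    f"{atom_x:.7f} 0.0 0.0 "
                    f"{i + spec.auth_offset} {auth_chain} 1"
                )
        x = coords["C"] + breaks.get(i, PEPTIDE_BOND)
    lines.append("#")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# reference sets


def toy_lineage_rows() -> list[tuple[int, int, int, int, int]]:
    """Synthetic taxa: (taxid, species, genus, family, order).

    101/102 share a genus, 103 shares only the family, 104 only the order,
    and 105 is unrelated.
    """
    return [
        (101, 101, 201, 301, 401),
        (102, 102, 201, 301, 401),
        (103, 103, 202, 301, 401),
        (104, 104, 203, 302, 401),
        (105, 105, 204, 303, 402),
    ]


def lineage_text(rows=None) -> str:
    rows = rows if rows is not None else toy_lineage_rows()
    return "".join("\t".join(str(v) for v in row) + "\n" for row in rows)


@dataclass
class ReferenceSetFixture:
    base_sequence: str
    accessions: list[str]
    sequences: dict[str, str]
    fasta_text: str
    taxonomy_text: str
    annotation_text: str
    xref_text: str
    lineage_text: str

    def write(self, directory: str | Path) -> dict[str, Path]:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        paths = {
            "fasta": directory / "references.fasta",
            "taxonomy": directory / "taxonomy.tsv",
            "annotation": directory / "annotation.tsv",
            "xref": directory / "xref.tsv",
            "lineage": directory / "lineage.tsv",
        }
        paths["fasta"].write_text(self.fasta_text)
        paths["taxonomy"].write_text(self.taxonomy_text)
        paths["annotation"].write_text(self.annotation_text)
        paths["xref"].write_text(self.xref_text)
        paths["lineage"].write_text(self.lineage_text)
        return paths


def _mutate(
    sequence: str, n_mutations: int, rng: random.Random, protect_ends: int = 0
) -> str:
    """Substitute at uniformly drawn positions without replacement (no indels).

    ``protect_ends`` keeps that many residues at each end unmutated, so
    terminal mismatches cannot be trimmed away by the local aligner.
    """
    candidates = range(protect_ends, len(sequence) - protect_ends)
    positions = rng.sample(candidates, n_mutations)
    letters = list(sequence)
    for pos in positions:
        alternatives = [a for a in STANDARD_AA if a != letters[pos]]
        letters[pos] = rng.choice(alternatives)
    return "".join(letters)


def make_reference_set(
    n: int,
    mutation_rates: list[float] | float = 0.0,
    datasets: list[str] | None = None,
    tax_ids: list[int] | None = None,
    annotation_scores: list[int] | None = None,
    xref_counts: list[int] | None = None,
    base_length: int = 100,
    base_sequence: str | None = None,
    protect_ends: int = 0,
    seed: int = 0,
) -> ReferenceSetFixture:
    """Reference FASTA + metadata tables with controlled identity to a base
    sequence and controlled lineage relationships.

    ``datasets`` entries are ``"sp"`` (reviewed) or ``"tr"`` (unreviewed);
    accessions are ``P90001..`` for sp and ``Q90001..`` for tr records.
    """
    if n < 1:
        raise FixtureError("n must be >= 1")
    rng = random.Random(seed)
    if base_sequence is None:
        base_sequence = "".join(rng.choice(STANDARD_AA) for _ in range(base_length))
    if isinstance(mutation_rates, (int, float)):
        mutation_rates = [float(mutation_rates)] * n
    datasets = datasets or ["sp"] * n
    tax_ids = tax_ids or [101] * n
    annotation_scores = annotation_scores or [
        5 if ds == "sp" else 0 for ds in datasets
    ]
    xref_counts = xref_counts or [0] * n
    for name, values in (
        ("mutation_rates", mutation_rates),
        ("datasets", datasets),
        ("tax_ids", tax_ids),
        ("annotation_scores", annotation_scores),
        ("xref_counts", xref_counts),
    ):
        if len(values) != n:
            raise FixtureError(f"{name} must have length {n}")

    fasta, taxonomy, annotation, xref = [], [], [], []
    accessions, sequences = [], {}
    for i in range(n):
        prefix = "P" if datasets[i] == "sp" else "Q"
        accession = f"{prefix}9{i + 1:04d}"
        name = f"TST{i + 1}_SYNTH"
        n_mutations = round(mutation_rates[i] * len(base_sequence))
        sequence = _mutate(base_sequence, n_mutations, rng, protect_ends)
        fasta.append(f">{datasets[i]}|{accession}|{name} OX={tax_ids[i]} SV=1")
        for j in range(0, len(sequence), 60):
            fasta.append(sequence[j : j + 60])
        taxonomy.append(f"{accession}\t{tax_ids[i]}")
        annotation.append(f"{accession}\t{annotation_scores[i]}")
        xref.append(f"{accession}\t{xref_counts[i]}")
        accessions.append(accession)
        sequences[accession] = sequence

    return ReferenceSetFixture(
        base_sequence=base_sequence,
        accessions=accessions,
        sequences=sequences,
        fasta_text="\n".join(fasta) + "\n",
        taxonomy_text="\n".join(taxonomy) + "\n",
        annotation_text="\n".join(annotation) + "\n",
        xref_text="\n".join(xref) + "\n",
        lineage_text=lineage_text(),
    )


# ---------------------------------------------------------------------------
# alignment-artefact case


@dataclass
class IsolatedArtifactCase:
    """A structure/reference pair whose naive best local alignment places one
    isolated residue inside an extended gap, plus the ground truth."""

    structure_cif: str
    structure_spec: StructureSpec
    query_sequence: str
    reference_sequence: str
    reference_accession: str
    isolated_query_position: int  # 1-based position of the spurious match


def make_isolated_artifact_case(seed: int = 0, max_retries: int = 20) -> IsolatedArtifactCase:
    """Construct the artefact case and verify it against the aligner.

    The reference carries a 10-residue stretch absent from the structure's
    sample sequence except for a single glycine, which the local aligner
    prefers to match inside the gap.  The glycine is unobserved in the
    coordinates, so refinement must un-align it into one contiguous gap.
    """
    params = AlignerParams()
    refinement = RefinementParams()
    for attempt in range(max_retries):
        rng = random.Random(seed * 1009 + attempt)
        # tryptophan in a bed of aspartates: the isolated W-W match scores
        # high while W absorbed into either flank as a mismatch scores low,
        # so the optimal local alignment provably isolates it
        flank_a = "".join(
            rng.choice(STANDARD_AA.replace("W", "")) for _ in range(30)
        )
        flank_b = "".join(
            rng.choice(STANDARD_AA.replace("W", "")) for _ in range(40)
        )
        gap_region = ["D"] * 10
        gap_region[5] = "W"
        reference = flank_a + "".join(gap_region) + flank_b
        query = flank_a + "W" + flank_b
        g_position = len(flank_a) + 1

        alignments = local_alignments(query, reference, params)
        if len(alignments) != 1:
            continue
        labels = classify_runs(alignments[0], refinement)
        isolated_runs = _isolated_run_count(labels)
        if isolated_runs != 1:
            continue

        observed = [True] * len(query)
        observed[g_position - 1] = False
        spec = StructureSpec(
            sequence=query,
            entry_id="art1",
            observed=observed,
            seed=seed,
        )
        cif = make_toy_structure(spec)
        # verify the ground truth end to end
        entity = parse_polymer_entities(cif)[0]
        refined, audit = refine_alignment(
            alignments[0], entity.chains[0], refinement
        )
        if any(a["action"] == "unalign" for a in audit) and not _isolated_run_count(
            classify_runs(refined, refinement)
        ):
            return IsolatedArtifactCase(
                structure_cif=cif,
                structure_spec=spec,
                query_sequence=query,
                reference_sequence=reference,
                reference_accession="P95000",
                isolated_query_position=g_position,
            )
    raise FixtureError("could not construct the artefact case; retries exhausted")


def _isolated_run_count(labels: list[str]) -> int:
    count = 0
    previous = None
    for label in labels:
        if label == ISOLATED and previous != ISOLATED:
            count += 1
        previous = label
    return count


# ---------------------------------------------------------------------------
# toy CCD


def make_toy_ccd() -> str:
    """A minimal components file: ALA, GLY, MET, MSE (parent MET) and XCC,
    a fake component with non-standard backbone atom names."""
    return """\
data_ALA
_chem_comp.id ALA
_chem_comp.one_letter_code A
loop_
_chem_comp_atom.comp_id
_chem_comp_atom.atom_id
_chem_comp_atom.type_symbol
_chem_comp_atom.pdbx_backbone_atom_flag
ALA N N Y
ALA CA C Y
ALA C C Y
ALA O O Y
ALA CB C N
#
data_GLY
_chem_comp.id GLY
_chem_comp.one_letter_code G
loop_
_chem_comp_atom.comp_id
_chem_comp_atom.atom_id
_chem_comp_atom.type_symbol
_chem_comp_atom.pdbx_backbone_atom_flag
GLY N N Y
GLY CA C Y
GLY C C Y
GLY O O Y
#
data_MET
_chem_comp.id MET
_chem_comp.one_letter_code M
loop_
_chem_comp_atom.comp_id
_chem_comp_atom.atom_id
_chem_comp_atom.type_symbol
_chem_comp_atom.pdbx_backbone_atom_flag
MET N N Y
MET CA C Y
MET C C Y
MET O O Y
MET SD S N
#
data_MSE
_chem_comp.id MSE
_chem_comp.one_letter_code M
_chem_comp.mon_nstd_parent_comp_id MET
loop_
_chem_comp_atom.comp_id
_chem_comp_atom.atom_id
_chem_comp_atom.type_symbol
_chem_comp_atom.pdbx_backbone_atom_flag
MSE N N Y
MSE CA C Y
MSE C C Y
MSE O O Y
MSE SE SE N
#
data_XCC
_chem_comp.id XCC
_chem_comp.one_letter_code ?
loop_
_chem_comp_atom.comp_id
_chem_comp_atom.atom_id
_chem_comp_atom.type_symbol
_chem_comp_atom.pdbx_backbone_atom_flag
XCC N1 N Y
XCC CA1 C Y
XCC C1 C Y
XCC O1 O Y
#
"""
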