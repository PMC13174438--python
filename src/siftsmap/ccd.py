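"""Chemical Component Dictionary (CCD) access.

A CCD ``components.cif`` file is a multi-block mmCIF file with one data
block per chemical component.  This module extracts the two pieces of
information the pipeline needs:

* the canonical one-letter code of a component (directly from
  ``_chem_comp.one_letter_code`` or via its standard parent component),
* the names of the backbone nitrogen / carbon atoms used for the
  peptide-connectivity check.

Backbone atoms are taken from ``_chem_comp_atom`` rows flagged with
``pdbx_backbone_atom_flag`` when that item is present: the first
nitrogen-element backbone atom is the amide nitrogen and the last
carbon-element backbone atom is the carbonyl carbon (CCD convention lists
N, CA, C, O in order).  Without the flag, atoms literally named ``N`` and
``C`` are used.  Components not covered by either rule fall back to
``("N", "C")``.
"""
from __future__ import annotations

import gzip
import io
import os
import warnings
from dataclasses import dataclass

from biotite.structure.io.pdbx import CIFFile

from .residues import ONE_TO_THREE, THREE_TO_ONE

_FALLBACK = ("N", "C")


@dataclass(frozen=True)
class Component:
    """One CCD component reduced to what the pipeline consumes."""

    comp_id: str
    one_letter: str          # 'X' when unresolvable
    parent_comp_id: str | None
    n_atom: str
    c_atom: str


class ComponentDictionary:
    """In-memory lookup over a parsed CCD components file."""

    def __init__(self, components: dict[str, Component]):
        self._components = components

    @classmethod
    def from_file(cls, path: str | os.PathLike) -> "ComponentDictionary":
        with open(path, "rb") as fh:
            data = fh.read()
        if data[:2] == b"\x1f\x8b":
            data = gzip.decompress(data)
        return cls.from_text(data.decode())

    @classmethod
    def from_text(cls, text: str) -> "ComponentDictionary":
        cif = CIFFile.read(io.StringIO(text))
        components: dict[str, Component] = {}
        for block_name in cif.keys():
            block = cif[block_name]
            if "chem_comp" not in block:
                continue
            chem_comp = block["chem_comp"]
            comp_id = str(chem_comp["id"].as_item())
            parent = None
            if "mon_nstd_parent_comp_id" in chem_comp:
                raw = str(chem_comp["mon_nstd_parent_comp_id"].as_item())
                if raw not in ("?", ".", ""):
                    # polymeric parents are comma-separated; keep the first
                    parent = raw.split(",")[0].strip().upper()
            one = "X"
            if "one_letter_code" in chem_comp:
                raw = str(chem_comp["one_letter_code"].as_item()).upper()
                if len(raw) == 1 and raw in THREE_TO_ONE.values():
                    one = raw
            if one == "X" and parent is not None:
                one = THREE_TO_ONE.get(parent, "X")
            if one == "X" and comp_id.upper() in THREE_TO_ONE:
                one = THREE_TO_ONE[comp_id.upper()]
            n_atom, c_atom = _backbone_from_block(block)
            components[comp_id.upper()] = Component(
                comp_id=comp_id.upper(),
                one_letter=one,
                parent_comp_id=parent,
                n_atom=n_atom,
                c_atom=c_atom,
            )
        return cls(components)

    def __contains__(self, comp_id: str) -> bool:
        return comp_id.upper() in self._components

    def get(self, comp_id: str) -> Component | None:
        return self._components.get(comp_id.upper())

    def one_letter(self, comp_id: str) -> str:
        comp = self.get(comp_id)
        if comp is not None:
            return comp.one_letter
        return THREE_TO_ONE.get(comp_id.upper(), "X")


def _backbone_from_block(block) -> tuple[str, str]:
    if "chem_comp_atom" not in block:
        return _FALLBACK
    atoms = block["chem_comp_atom"]
    names = [str(v) for v in atoms["atom_id"].as_array(str)]
    elements = [str(v).upper() for v in atoms["type_symbol"].as_array(str)]
    if "pdbx_backbone_atom_flag" in atoms:
        flags = [str(v).upper() for v in atoms["pdbx_backbone_atom_flag"].as_array(str)]
        backbone = [
            (name, elem)
            for name, elem, flag in zip(names, elements, flags)
            if flag == "Y"
        ]
        n_atoms = [name for name, elem in backbone if elem == "N"]
        c_atoms = [name for name, elem in backbone if elem == "C"]
        if n_atoms and c_atoms:
            return n_atoms[0], c_atoms[-1]
    if "N" in names and "C" in names:
        return "N", "C"
    return _FALLBACK


def backbone_atom_names(
    chem_comp_id: str, ccd: ComponentDictionary | None = None
) -> tuple[str, str]:
    """Resolve (amide-N, carbonyl-C) atom names for a component.

    Falls back to ``("N", "C")`` — with a warning for components that are
    neither standard amino acids nor present in the supplied dictionary.
    """
    if ccd is not None:
        comp = ccd.get(chem_comp_id)
        if comp is not None:
            return comp.n_atom, comp.c_atom
    if chem_comp_id.upper() in ONE_TO_THREE.values():
        return _FALLBACK
    warnings.warn(
        f"component {chem_comp_id!r} not in CCD; assuming backbone atoms N/C",
        stacklevel=2,
    )
    return _FALLBACK
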