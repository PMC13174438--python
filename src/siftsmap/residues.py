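"""Amino-acid code tables.

Only the 20 standard residues are enumerated; everything else resolves
through the component dictionary (see :mod:`siftsmap.ccd`) or falls back
to ``'X'``.
"""

STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"

#: letters permitted in sample/reference sequences
VALID_LETTERS = frozenset(STANDARD_AA + "X")

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}

ONE_TO_THREE = {one: three for three, one in THREE_TO_ONE.items()}

STANDARD_COMPONENTS = frozenset(THREE_TO_ONE)


def is_standard(chem_comp_id: str) -> bool:
    """True if *chem_comp_id* is one of the 20 standard amino-acid components."""
    return chem_comp_id.upper() in STANDARD_COMPONENTS
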