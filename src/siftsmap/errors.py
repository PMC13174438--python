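"""Exception hierarchy shared across the package."""


class SiftsmapError(Exception):
    """Base class for all package-specific errors."""


class MmcifParseError(SiftsmapError):
    """Raised when a PDBx/mmCIF file is malformed.

    The message names the offending category when it can be determined.
    """

    def __init__(self, message: str, category: str | None = None):
        self.category = category
        if category:
            message = f"{message} (category: _{category})"
        super().__init__(message)


class NoPolymerEntityError(SiftsmapError):
    """Raised when a syntactically valid mmCIF contains no polypeptide entity."""


class InputError(SiftsmapError):
    """Invalid user-supplied value (bad sequence letters, out-of-range parameter)."""


class ConsistencyError(SiftsmapError):
    """Cross-referenced records disagree (unknown entity, overlapping alignments)."""


class MissingTaxonomyError(SiftsmapError):
    """A reference sequence identifier is absent from the taxonomy map."""

    def __init__(self, accession: str):
        self.accession = accession
        super().__init__(
            f"identifier {accession!r} is missing from the taxonomy map; "
            "a taxid is required for every reference sequence"
        )


class DuplicateAccessionError(SiftsmapError):
    """The same accession occurs more than once in a reference set."""


class WriteError(SiftsmapError):
    """An output file failed verification after writing."""


class FixtureError(SiftsmapError):
    """A synthetic-data specification is internally inconsistent."""
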