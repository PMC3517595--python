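"""Exception hierarchy shared across the package."""


class MotifStructError(Exception):
    """Base class for all package-specific errors."""


class MotifParseError(MotifStructError, ValueError):
    """Malformed consensus pattern text."""

    def __init__(self, message: str, position: int | None = None):
        self.position = position
        if position is not None:
            message = f"{message} (at character {position})"
        super().__init__(message)


class LexiconSizeError(MotifStructError, ValueError):
    """Enumeration refused because the lexical set exceeds the cap."""

    def __init__(self, size: int, cap: int):
        self.size = size
        self.cap = cap
        super().__init__(
            f"lexical set has {size} members, exceeding the cap of {cap}; "
            "enumeration refused"
        )


class EmptyStructureError(MotifStructError, ValueError):
    """PDB text contained no ATOM/HETATM records."""


class StructureLookupError(MotifStructError, KeyError):
    """A chain or residue range is not present in the structure."""


class ExtractionError(MotifStructError, ValueError):
    """A selected atom is missing from a residue being extracted."""


class PDBFormatError(MotifStructError, ValueError):
    """A value cannot be represented in fixed-column PDB format."""


class SizeMismatchError(MotifStructError, ValueError):
    """Two coordinate sets being compared have unequal atom counts."""


class WeightSchemeMismatchError(MotifStructError, ValueError):
    """A score and threshold computed under different weight schemes."""


class LibraryError(MotifStructError, ValueError):
    """Invalid request against the secondary-structure library."""
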