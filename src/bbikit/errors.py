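"""Exception hierarchy.

Three failure families are distinguished so callers (and the CLI exit-code
mapping) can react differently: text that cannot be parsed, inputs that parse
but violate a contract, and binary files that are structurally broken.
"""


class BbiError(Exception):
    """Base class for all errors raised by this package."""


class ParseError(BbiError):
    """A text input (bedGraph, Wiggle, BED, chrom.sizes, autoSql) is malformed.

    Carries ``line`` (1-based line number) or ``offset`` (character offset,
    for autoSql) when known.
    """

    def __init__(self, message: str, *, line: int | None = None, offset: int | None = None):
        if line is not None:
            message = f"line {line}: {message}"
        elif offset is not None:
            message = f"offset {offset}: {message}"
        super().__init__(message)
        self.line = line
        self.offset = offset


class ValidationError(BbiError):
    """Input parses but violates a contract (unsorted, overlapping, out of bounds...)."""


class BbiFormatError(BbiError):
    """A binary BBI structure is corrupt, truncated, or not a BBI file at all."""


class ChromNotFoundError(BbiError):
    """A queried chromosome is absent from the file's chromosome table."""

    def __init__(self, chrom: str):
        super().__init__(f"chromosome not found in file: {chrom!r}")
        self.chrom = chrom


class WrongFileKindError(BbiError):
    """A BigWig-only operation was applied to a BigBed or vice versa."""
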