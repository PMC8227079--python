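"""Exception types shared across the pipeline."""


class MitescapeError(Exception):
    """Base class for all pipeline errors."""


class ParameterError(MitescapeError, ValueError):
    """A parameter violates its documented constraint."""


class CapacityError(MitescapeError):
    """No remaining space to place an element or gene."""


class UnknownReferenceError(MitescapeError, KeyError):
    """A contig / gene / feature id is not present in the given reference set."""


class FastaParseError(MitescapeError):
    """Malformed FASTA record; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        suffix = f" (line {line})" if line is not None else ""
        super().__init__(message + suffix)


class Gff3StructureError(MitescapeError):
    """GFF3 features are structurally inconsistent (orphan child, CDS outside exons, ...)."""


class DegenerateTableError(MitescapeError):
    """A contingency table has a zero margin or is otherwise degenerate."""
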