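"""Exception hierarchy for the spherical package."""


class SphericalError(Exception):
    """Base class for all errors raised by this package."""


class ParseError(SphericalError):
    """A sequence or table file is malformed."""


class AssemblyError(SphericalError):
    """The assembler cannot proceed (e.g. no usable kmers)."""


class BackendError(SphericalError):
    """An assembler backend is unknown or unavailable."""


class AlignmentError(SphericalError):
    """Invalid alignment input (e.g. empty contig set for indexing)."""
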