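"""Exception hierarchy for mdop.

Every error the toolkit raises deliberately derives from :class:`MdopError`,
so callers (and the CLI) can catch one type. Subclasses also inherit the
closest builtin (``ValueError``, ``OSError``, ``FileExistsError``) so the
errors behave sensibly in generic code.
"""


class MdopError(Exception):
    """Base class for all errors raised by mdop operations."""


class InvalidOperationError(MdopError, ValueError):
    """An operation name outside the fixed set of nine."""


class ContractViolationError(MdopError, ValueError):
    """A naming context missing a required component (file type or index)."""


class InputPathError(MdopError, OSError):
    """An input path that does not exist or cannot be read."""


class OutputPathError(MdopError, OSError):
    """An output location that does not exist or cannot be written."""


class AlreadyExistsError(MdopError, FileExistsError):
    """A rendered output name collides with an existing file or folder.

    Operations never overwrite: a collision aborts the run so no data is
    silently replaced.
    """


class OversizeFileError(MdopError, ValueError):
    """A single file exceeds the per-folder size cap and can never be packed."""


class EmptyListError(MdopError, ValueError):
    """A file-name list that contains no usable (non-blank) lines."""


class FastaError(MdopError, ValueError):
    """Base class for FASTA parsing and transformation errors."""


class NotFastaError(FastaError):
    """Input that contains no ``>`` definition line at all."""


class MalformedRecordError(FastaError):
    """A FASTA record with an empty header, an empty sequence, or a stray ``>``."""


class EmptyAfterDegapError(FastaError):
    """A record whose sequence is entirely gaps; removing them leaves nothing."""


class MultiLineInputError(FastaError):
    """A multi-line FASTA handed to a transform that requires single-line input."""


class FixtureSpecError(MdopError, ValueError):
    """A synthetic-data specification that is internally contradictory."""
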