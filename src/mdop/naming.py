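"""Output-name conventions shared by every operation.

All nine operations stamp their outputs with the run date followed by the
operation name: ``YYYYMMDD_<op>[_TYP][_#][.ext]``. The date prefix is always
eight zero-padded digits; the ``TYP`` component (``JPG``/``AB1``/``FAS``)
appears only for the three type-parameterized operations, and the trailing
index only for the size-partitioning operation, where it counts output
folders from 1.

The run date defaults to today but is injectable everywhere so runs (and
tests) are reproducible.
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass

from .errors import ContractViolationError, InvalidOperationError

__all__ = ["OP_NAMES", "NamingContext", "render_name"]

#: The fixed set of operation tokens.
OP_NAMES = frozenset(
    {
        "target_file_list",
        "recursive_copy",
        "max_packs",
        "copy_by_list",
        "degap",
        "rank_seq",
        "head_derep",
        "seq_derep",
        "multi_to_single_fasta",
    }
)

_VALID_TYPES = ("JPG", "AB1", "FAS")

# Ops whose name carries the file-type component.
_TYPE_OPS = frozenset({"target_file_list", "recursive_copy", "max_packs"})

# File (vs folder) outputs and their extensions.
_FILE_EXT = {
    "target_file_list": ".txt",
    "degap": ".fas",
    "rank_seq": ".fas",
    "head_derep": ".fas",
    "seq_derep": ".fas",
    "multi_to_single_fasta": ".fas",
}


def _normalize_type(file_type) -> str | None:
    if file_type is None:
        return None
    value = getattr(file_type, "value", file_type)
    value = str(value).upper()
    if value not in _VALID_TYPES:
        raise ContractViolationError(
            f"file type must be one of {_VALID_TYPES!r}, got {file_type!r}"
        )
    return value


@dataclass(frozen=True)
class NamingContext:
    """Everything an output name is derived from.

    Parameters
    ----------
    run_date
        Calendar date stamped into the name (eight digits, YYYYMMDD).
    op_name
        One of the nine operation tokens in :data:`OP_NAMES`.
    file_type
        ``"JPG"``/``"AB1"``/``"FAS"`` (or a :class:`~mdop.fsops.TargetFileType`);
        required exactly for ``target_file_list``, ``recursive_copy`` and
        ``max_packs``.
    index
        1-based folder counter; required exactly for ``max_packs``.
    """

    run_date: datetime.date
    op_name: str
    file_type: object | None = None
    index: int | None = None


def render_name(ctx: NamingContext) -> str:
    """Render the exact output file or folder name for a context.

    Pure function: identical contexts give identical strings, and the first
    eight characters always parse back to ``ctx.run_date``.

    Raises
    ------
    InvalidOperationError
        If ``ctx.op_name`` is not one of the nine operation tokens.
    ContractViolationError
        If a required component (file type, index) is missing, if one is
        supplied for an operation that does not use it, or if the index is
        not a positive integer.
    """
    op = ctx.op_name
    if op not in OP_NAMES:
        raise InvalidOperationError(f"unknown operation {op!r}")

    ftype = _normalize_type(ctx.file_type)
    if op in _TYPE_OPS:
        if ftype is None:
            raise ContractViolationError(f"{op} requires a file type (JPG/AB1/FAS)")
    elif ftype is not None:
        raise ContractViolationError(f"{op} does not take a file type")

    if op == "max_packs":
        if ctx.index is None:
            raise ContractViolationError("max_packs requires a folder index")
        if not isinstance(ctx.index, int) or isinstance(ctx.index, bool) or ctx.index < 1:
            raise ContractViolationError(
                f"folder index must be a positive integer, got {ctx.index!r}"
            )
    elif ctx.index is not None:
        raise ContractViolationError(f"{op} does not take an index")

    d = ctx.run_date
    parts = [f"{d.year:04d}{d.month:02d}{d.day:02d}", op]
    if ftype is not None:
        parts.append(ftype)
    if op == "max_packs":
        parts.append(str(ctx.index))
    return "_".join(parts) + _FILE_EXT.get(op, "")


def render(
    op_name: str,
    run_date: datetime.date | None = None,
    file_type=None,
    index: int | None = None,
) -> str:
    """Convenience wrapper around :func:`render_name`.

    ``run_date`` defaults to the local calendar date at invocation.
    """
    if run_date is None:
        run_date = datetime.date.today()
    return render_name(NamingContext(run_date, op_name, file_type, index))
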