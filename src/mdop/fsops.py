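"""File-level operations: discover, list, copy, partition, and subset.

These are the staging steps that come before a repository upload: pull every
specimen image or AB1 trace out of a cascading project tree into one folder,
write a manifest of what is there, split a folder into upload-sized packs,
or copy exactly the files named in a curation list.

All operations are non-destructive: sources are only ever read and copied,
never moved or modified, and a rendered output name that already exists
aborts the run rather than overwriting.
"""

from __future__ import annotations

import datetime
import enum
import logging
import os
import shutil
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from . import naming
from .errors import (
    AlreadyExistsError,
    EmptyListError,
    InputPathError,
    OutputPathError,
    OversizeFileError,
)

__all__ = [
    "TargetFileType",
    "FileEntry",
    "PackPlan",
    "scan_targets",
    "write_file_list",
    "recursive_copy",
    "plan_packs",
    "execute_packs",
    "parse_file_list",
    "copy_by_list",
]

logger = logging.getLogger(__name__)


class TargetFileType(enum.Enum):
    """The three file categories handled during submission staging.

    ``FAS`` covers both the ``.fasta`` and ``.fas`` spellings; matching is
    case-insensitive throughout (field cameras and sequencers commonly emit
    upper-case extensions).
    """

    JPG = "JPG"
    AB1 = "AB1"
    FAS = "FAS"

    @property
    def extensions(self) -> frozenset[str]:
        return _EXTENSIONS[self]

    def matches(self, path: Path | str) -> bool:
        """True if ``path`` has one of this type's extensions (any case)."""
        suffix = Path(path).suffix
        return suffix[1:].lower() in self.extensions if suffix else False

    @classmethod
    def coerce(cls, value: "TargetFileType | str") -> "TargetFileType":
        if isinstance(value, cls):
            return value
        try:
            return cls[str(value).upper()]
        except KeyError:
            raise ValueError(
                f"file type must be one of JPG, AB1, FAS; got {value!r}"
            ) from None


_EXTENSIONS = {
    TargetFileType.JPG: frozenset({"jpg"}),
    TargetFileType.AB1: frozenset({"ab1"}),
    TargetFileType.FAS: frozenset({"fas", "fasta"}),
}


@dataclass(frozen=True)
class FileEntry:
    """A discovered file: absolute path, base name, and on-disk byte size."""

    absolute_path: Path
    base_name: str
    size_bytes: int

    @classmethod
    def from_path(cls, path: Path) -> "FileEntry":
        path = Path(path).resolve()
        return cls(path, path.name, path.stat().st_size)


@dataclass(frozen=True)
class PackPlan:
    """An assignment of files to indexed output folders under a size cap.

    ``packs`` partitions the planned entries: every entry appears in exactly
    one pack, each pack's total ``size_bytes`` is at most
    ``max_folder_bytes``, and concatenating the packs reproduces the input
    order.
    """

    max_folder_bytes: int
    packs: tuple[tuple[FileEntry, ...], ...] = field(default_factory=tuple)


def _check_readable_dir(root: Path) -> Path:
    root = Path(root)
    if not root.is_dir():
        raise InputPathError(f"not a readable directory: {root}")
    return root.resolve()


def scan_targets(
    root: Path | str,
    ftype: TargetFileType | str,
    recursive: bool = True,
    *,
    exclude: Iterable[Path] = (),
) -> list[FileEntry]:
    """Find all regular files of one target type under ``root``.

    With ``recursive=True`` the whole tree below ``root`` is searched;
    otherwise only ``root`` itself. Symbolic links are not followed.
    Directories listed in ``exclude`` (and everything below them) are
    skipped. The result is ordered lexicographically by full path, so a
    given tree always scans to the same list.
    """
    root = _check_readable_dir(root)
    ftype = TargetFileType.coerce(ftype)
    excluded = {Path(p).resolve() for p in exclude}

    found: list[Path] = []
    if recursive:
        for dirpath, dirnames, filenames in os.walk(root, followlinks=False):
            here = Path(dirpath)
            dirnames[:] = sorted(
                d for d in dirnames if (here / d).resolve() not in excluded
            )
            for name in filenames:
                p = here / name
                if ftype.matches(p) and p.is_file() and not p.is_symlink():
                    found.append(p)
    else:
        for p in root.iterdir():
            if ftype.matches(p) and p.is_file() and not p.is_symlink():
                found.append(p)

    found.sort(key=lambda p: str(p.resolve()))
    return [FileEntry.from_path(p) for p in found]


def write_file_list(
    entries: Sequence[FileEntry],
    dest: Path | str,
    ftype: TargetFileType | str,
    run_date: datetime.date | None = None,
) -> Path:
    """Save a manifest of discovered files as a text file in ``dest``.

    One record per line, ``absolute_path<TAB>base_name``, in the order given.
    The file is named ``YYYYMMDD_target_file_list_TYP.txt``.
    """
    dest = Path(dest)
    if not dest.is_dir():
        raise OutputPathError(f"not a writable directory: {dest}")
    ftype = TargetFileType.coerce(ftype)
    out = dest / naming.render("target_file_list", run_date, ftype)
    if out.exists():
        raise AlreadyExistsError(f"output already exists: {out}")
    with open(out, "w", encoding="utf-8") as fh:
        for entry in entries:
            fh.write(f"{entry.absolute_path}\t{entry.base_name}\n")
    return out


def _unique_destination(folder: Path, base_name: str, taken: set[str]) -> Path:
    """Resolve a base-name collision by suffixing ``_1``, ``_2``, ... ."""
    if base_name not in taken:
        taken.add(base_name)
        return folder / base_name
    stem, dot, ext = base_name.partition(".")
    i = 1
    while True:
        candidate = f"{stem}_{i}{dot}{ext}" if dot else f"{stem}_{i}"
        if candidate not in taken:
            logger.warning(
                "base-name collision: copying %r as %r", base_name, candidate
            )
            taken.add(candidate)
            return folder / candidate
        i += 1


def recursive_copy(
    root: Path | str,
    ftype: TargetFileType | str,
    run_date: datetime.date | None = None,
) -> Path:
    """Copy every matching file below ``root`` into one new folder.

    The folder ``YYYYMMDD_recursive_copy_TYP`` is created directly under
    ``root`` and is excluded from the scan, so re-running on the same tree
    never copies a previous run's output. Files from different
    subdirectories that share a base name are kept by renaming the later
    copies with a ``_1``, ``_2``, ... suffix (logged); nothing is silently
    dropped.
    """
    root = _check_readable_dir(root)
    ftype = TargetFileType.coerce(ftype)
    out = root / naming.render("recursive_copy", run_date, ftype)
    if out.exists():
        raise AlreadyExistsError(f"output already exists: {out}")

    out.mkdir()  # claim the name first, then scan around it
    entries = scan_targets(root, ftype, recursive=True, exclude=[out])
    taken: set[str] = set()
    for entry in entries:
        shutil.copy2(entry.absolute_path, _unique_destination(out, entry.base_name, taken))
    return out


def plan_packs(
    entries: Sequence[FileEntry],
    max_folder_bytes: int,
) -> PackPlan:
    """Partition files into folders none of which exceeds a byte cap.

    Packing is sequential first-fit in the given order: each file joins the
    current pack unless that would push it past the cap, in which case a new
    pack is opened. Deterministic and order-stable, not an optimal
    bin-packing.

    Raises
    ------
    OversizeFileError
        If any single file is larger than the cap (it could never fit).
    """
    if max_folder_bytes <= 0:
        raise ValueError(f"max_folder_bytes must be positive, got {max_folder_bytes}")
    for entry in entries:
        if entry.size_bytes > max_folder_bytes:
            raise OversizeFileError(
                f"{entry.base_name} ({entry.size_bytes} bytes) exceeds the "
                f"folder cap of {max_folder_bytes} bytes"
            )

    packs: list[tuple[FileEntry, ...]] = []
    current: list[FileEntry] = []
    current_size = 0
    for entry in entries:
        if current and current_size + entry.size_bytes > max_folder_bytes:
            packs.append(tuple(current))
            current, current_size = [], 0
        current.append(entry)
        current_size += entry.size_bytes
    if current:
        packs.append(tuple(current))
    return PackPlan(max_folder_bytes, tuple(packs))


def execute_packs(
    plan: PackPlan,
    target: Path | str,
    ftype: TargetFileType | str,
    run_date: datetime.date | None = None,
) -> list[Path]:
    """Materialize a :class:`PackPlan`: one folder per pack, files copied in.

    Folders are named ``YYYYMMDD_max_packs_TYP_#`` with ``#`` counting from 1
    and are created inside ``target``. Returns the folder paths in index
    order; an empty plan creates nothing.
    """
    target = Path(target)
    if not target.is_dir():
        raise OutputPathError(f"not a writable directory: {target}")
    ftype = TargetFileType.coerce(ftype)

    folders = [
        target / naming.render("max_packs", run_date, ftype, index=i)
        for i in range(1, len(plan.packs) + 1)
    ]
    for folder in folders:
        if folder.exists():
            raise AlreadyExistsError(f"output already exists: {folder}")
    for folder, pack in zip(folders, plan.packs):
        folder.mkdir()
        for entry in pack:
            shutil.copy2(entry.absolute_path, folder / entry.base_name)
    return folders


def parse_file_list(list_file: Path | str) -> list[str]:
    """Read a one-name-per-line text file into a list of file names.

    Blank lines (including the conventional single trailing one) are
    dropped; surrounding whitespace is trimmed; LF and CRLF both work.
    Duplicate names are preserved here — the copy step de-duplicates them.
    """
    list_file = Path(list_file)
    if not list_file.is_file():
        raise InputPathError(f"not a readable file: {list_file}")
    text = list_file.read_text(encoding="utf-8-sig")
    names = [line.strip() for line in text.splitlines()]
    names = [n for n in names if n]
    if not names:
        raise EmptyListError(f"file list contains no file names: {list_file}")
    return names


def copy_by_list(
    source: Path | str,
    names: Sequence[str],
    run_date: datetime.date | None = None,
    dest: Path | str | None = None,
) -> tuple[Path, list[str]]:
    """Copy the named files out of ``source`` into a new folder.

    Only ``source`` itself is searched — never its subdirectories; a listed
    file that exists only in a subdirectory is reported as missing. The
    output folder ``YYYYMMDD_copy_by_list`` is created under ``dest``
    (default: ``source``). Returns the folder path and the sorted list of
    requested names that had no match; missing names are reported, not
    fatal.
    """
    source = _check_readable_dir(source)
    dest = source if dest is None else Path(dest)
    if not dest.is_dir():
        raise OutputPathError(f"not a writable directory: {dest}")

    unique_names = list(dict.fromkeys(names))
    if len(unique_names) < len(names):
        logger.warning(
            "file list contains %d duplicate name(s); copying each file once",
            len(names) - len(unique_names),
        )

    out = Path(dest) / naming.render("copy_by_list", run_date)
    if out.exists():
        raise AlreadyExistsError(f"output already exists: {out}")

    present = {
        p.name: p for p in source.iterdir() if p.is_file() and not p.is_symlink()
    }
    out.mkdir()
    missing: list[str] = []
    for name in unique_names:
        if name in present:
            shutil.copy2(present[name], out / name)
        else:
            missing.append(name)
    return out, sorted(missing)
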