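"""Seeded synthetic inputs with known ground truth.

Two generators produce everything the toolkit operates on, so the whole
package is testable without downloading a single real file:

* :func:`generate_tree` builds a random directory tree of JPG / AB1 /
  FASTA / unrelated files. The JPG and AB1 blobs are opaque random bytes —
  faithful enough, because no operation ever opens them. The returned
  manifest is the oracle for discovery, copying and packing.
* :func:`generate_fasta` writes a multiple-sequence FASTA with controlled
  gapping, header duplication and sequence duplication, and records per-
  record inserted-gap counts plus the distinct-header and distinct-sequence
  tallies that the dereplication transforms must reproduce.

Both are pure functions of (spec, seed): the same spec always yields the
same bytes on disk.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field
from pathlib import Path

from .errors import FixtureSpecError, OutputPathError
from .fasta import FastaRecord

__all__ = [
    "TreeSpec",
    "FastaSpec",
    "Manifest",
    "FastaGroundTruth",
    "generate_tree",
    "generate_fasta",
]

_EXT_CHOICES = {
    "JPG": ("jpg", "JPG"),
    "AB1": ("ab1", "AB1"),
    "FAS": ("fas", "fasta", "FAS"),
    "other": ("txt", "csv", "png"),
}


@dataclass(frozen=True)
class TreeSpec:
    """Shape of a synthetic directory tree.

    ``type_mix`` gives the proportions of JPG, AB1, FAS and unrelated files
    (must sum to 1); ``duplicate_name_rate`` is the chance a new file reuses
    an existing base name from elsewhere in the tree, which exercises
    collision handling during recursive copies.
    """

    depth: int = 2
    files_per_dir: tuple[int, int] = (0, 4)
    type_mix: dict = field(
        default_factory=lambda: {"JPG": 0.35, "AB1": 0.35, "FAS": 0.2, "other": 0.1}
    )
    size_range_bytes: tuple[int, int] = (16, 256)
    duplicate_name_rate: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.depth < 0:
            raise FixtureSpecError("depth must be >= 0")
        lo, hi = self.files_per_dir
        if lo < 0 or hi < lo:
            raise FixtureSpecError(f"empty files_per_dir range: {self.files_per_dir}")
        lo, hi = self.size_range_bytes
        if lo < 0 or hi < lo:
            raise FixtureSpecError(f"empty size range: {self.size_range_bytes}")
        if not 0.0 <= self.duplicate_name_rate <= 1.0:
            raise FixtureSpecError("duplicate_name_rate must be in [0, 1]")
        if set(self.type_mix) - set(_EXT_CHOICES):
            raise FixtureSpecError(f"unknown type_mix keys: {sorted(self.type_mix)}")
        if abs(sum(self.type_mix.values()) - 1.0) > 1e-9:
            raise FixtureSpecError("type_mix proportions must sum to 1")


@dataclass(frozen=True)
class ManifestEntry:
    path: Path
    base_name: str
    size_bytes: int
    ftype: str  # JPG | AB1 | FAS | other


@dataclass
class Manifest:
    """Ground truth for a generated tree: every file plus per-type counts."""

    root: Path
    entries: list[ManifestEntry]
    counts: dict

    def paths_of_type(self, ftype: str) -> list[Path]:
        return sorted(e.path for e in self.entries if e.ftype == str(ftype).upper())

    def write_json(self, path: Path | str) -> Path:
        path = Path(path)
        payload = {
            "root": str(self.root),
            "counts": self.counts,
            "entries": [
                {
                    "path": str(e.path),
                    "base_name": e.base_name,
                    "size_bytes": e.size_bytes,
                    "ftype": e.ftype,
                }
                for e in self.entries
            ],
        }
        path.write_text(json.dumps(payload, indent=1), encoding="utf-8")
        return path


def generate_tree(spec: TreeSpec, root: Path | str) -> Manifest:
    """Create a random tree of target and decoy files under an empty root.

    Refuses a non-empty root (never mingles synthetic files with user
    data). Identical specs produce identical trees.
    """
    spec.validate()
    root = Path(root)
    if not root.is_dir():
        raise OutputPathError(f"not a directory: {root}")
    if any(root.iterdir()):
        raise OutputPathError(f"refusing to generate into non-empty directory: {root}")

    rng = random.Random(spec.seed)
    types = sorted(spec.type_mix)
    weights = [spec.type_mix[t] for t in types]
    entries: list[ManifestEntry] = []
    used_names: list[str] = []
    counter = 0

    def fill(directory: Path, depth_left: int) -> None:
        nonlocal counter
        n_files = rng.randint(*spec.files_per_dir)
        for _ in range(n_files):
            ftype = rng.choices(types, weights)[0]
            ext = rng.choice(_EXT_CHOICES[ftype])
            same_type = [n for n in used_names if n.rsplit(".", 1)[-1].lower() == ext.lower()]
            if same_type and rng.random() < spec.duplicate_name_rate:
                name = rng.choice(same_type)
            else:
                name = f"specimen_{counter:05d}.{ext}"
                counter += 1
            if (directory / name).exists():  # same dir cannot hold duplicates
                name = f"specimen_{counter:05d}.{ext}"
                counter += 1
            used_names.append(name)
            size = rng.randint(*spec.size_range_bytes)
            payload = rng.randbytes(size)
            path = directory / name
            path.write_bytes(payload)
            entries.append(ManifestEntry(path.resolve(), name, size, ftype))
        if depth_left > 0:
            for i in range(rng.randint(1, 3)):
                sub = directory / f"sub_{depth_left}_{i}"
                sub.mkdir()
                fill(sub, depth_left - 1)

    fill(root, spec.depth)
    counts = {t: sum(1 for e in entries if e.ftype == t) for t in types}
    return Manifest(root.resolve(), entries, counts)


@dataclass(frozen=True)
class FastaSpec:
    """Shape of a synthetic multiple-sequence FASTA.

    ``gap_fraction`` is the per-position chance of inserting a ``-``;
    ``duplicate_header_rate`` / ``duplicate_sequence_rate`` are the chances
    that a record reuses an earlier record's header / sequence;
    ``wrap_width`` of 0 writes single-line records, a positive value wraps
    sequence lines at that many columns (80 is the classic multi-line
    layout); ``lowercase_rate`` soft-masks bases to exercise
    case-insensitive sequence keying.
    """

    n_records: int = 20
    length_range: tuple[int, int] = (80, 400)
    gap_fraction: float = 0.0
    duplicate_header_rate: float = 0.0
    duplicate_sequence_rate: float = 0.0
    wrap_width: int = 0
    lowercase_rate: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_records < 1:
            raise FixtureSpecError("n_records must be >= 1")
        lo, hi = self.length_range
        if lo < 1 or hi < lo:
            raise FixtureSpecError(f"empty length range: {self.length_range}")
        for name in ("gap_fraction", "duplicate_header_rate",
                     "duplicate_sequence_rate", "lowercase_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise FixtureSpecError(f"{name} must be in [0, 1], got {v}")
        if self.wrap_width < 0:
            raise FixtureSpecError("wrap_width must be >= 0")
        if self.n_records < 2 and (
            self.duplicate_header_rate > 0 or self.duplicate_sequence_rate > 0
        ):
            raise FixtureSpecError(
                "duplication requires at least two records to duplicate between"
            )


@dataclass
class FastaGroundTruth:
    """What the generator wrote, with the counts the transforms must hit."""

    path: Path
    records: list[FastaRecord]  # as written, gaps included
    gaps_inserted: list[int]  # per record, aligned with `records`
    n_distinct_headers: int
    n_distinct_sequence_keys: int  # case-insensitive, gaps as written


def _random_sequence(rng: random.Random, spec: FastaSpec) -> tuple[str, int]:
    length = rng.randint(*spec.length_range)
    chars = []
    gaps = 0
    for _ in range(length):
        if spec.gap_fraction and rng.random() < spec.gap_fraction:
            chars.append("-")
            gaps += 1
        base = rng.choice("ACGT")
        if spec.lowercase_rate and rng.random() < spec.lowercase_rate:
            base = base.lower()
        chars.append(base)
    return "".join(chars), gaps


def generate_fasta(spec: FastaSpec, path: Path | str) -> FastaGroundTruth:
    """Write a synthetic FASTA and return its ground truth.

    Duplicated sequences are reused verbatim (same gaps, possibly
    case-flipped when ``lowercase_rate`` > 0, so they still share a
    case-insensitive key); duplicated headers reuse an earlier header
    verbatim. The distinct counts are tallied over the records as written.
    """
    spec.validate()
    path = Path(path)
    if not path.parent.is_dir():
        raise OutputPathError(f"not a writable directory: {path.parent}")

    rng = random.Random(spec.seed)
    records: list[FastaRecord] = []
    gaps_inserted: list[int] = []
    for i in range(spec.n_records):
        if i > 0 and rng.random() < spec.duplicate_header_rate:
            header = records[rng.randrange(i)].header
        else:
            header = f"MDOP|specimen_{i:04d}|COI-5P"
        if i > 0 and rng.random() < spec.duplicate_sequence_rate:
            j = rng.randrange(i)
            seq, gaps = records[j].sequence, gaps_inserted[j]
            if spec.lowercase_rate and rng.random() < spec.lowercase_rate:
                seq = seq.swapcase()
        else:
            seq, gaps = _random_sequence(rng, spec)
        records.append(FastaRecord(header, seq))
        gaps_inserted.append(gaps)

    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for record in records:
            fh.write(f">{record.header}\n")
            if spec.wrap_width > 0:
                for start in range(0, len(record.sequence), spec.wrap_width):
                    fh.write(record.sequence[start : start + spec.wrap_width] + "\n")
            else:
                fh.write(record.sequence + "\n")

    return FastaGroundTruth(
        path=path,
        records=records,
        gaps_inserted=gaps_inserted,
        n_distinct_headers=len({r.header for r in records}),
        n_distinct_sequence_keys=len({r.sequence.upper() for r in records}),
    )
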