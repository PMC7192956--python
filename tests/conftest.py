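"""Shared helpers: brute-force oracles kept independent of the implementation."""

import hashlib
from pathlib import Path

from mdop.fasta import FastaDocument, FastaRecord

# Extension table restated here on purpose: the oracles must not share code
# with mdop.fsops.
ORACLE_EXTS = {"JPG": {"jpg"}, "AB1": {"ab1"}, "FAS": {"fas", "fasta"}}


def oracle_walk(root, ftype, recursive=True, exclude=()):
    """Enumerate every matching file by explicit traversal (no os.walk)."""
    root = Path(root)
    excluded = {Path(p).resolve() for p in exclude}
    exts = ORACLE_EXTS[str(ftype)]

    def ext_ok(p: Path) -> bool:
        return bool(p.suffix) and p.suffix[1:].lower() in exts

    matches = []
    if recursive:
        stack = [root]
        while stack:
            d = stack.pop()
            for child in d.iterdir():
                if child.resolve() in excluded:
                    continue
                if child.is_dir() and not child.is_symlink():
                    stack.append(child)
                elif child.is_file() and not child.is_symlink() and ext_ok(child):
                    matches.append(child.resolve())
    else:
        matches = [
            p.resolve()
            for p in root.iterdir()
            if p.is_file() and not p.is_symlink() and ext_ok(p)
        ]
    return sorted(matches, key=str)


def sha256(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def checksum_tree(root, skip_under=()) -> dict:
    """Map of path-relative-to-root -> sha256 for every file in the tree."""
    root = Path(root)
    skipped = {Path(p).resolve() for p in skip_under}
    out = {}
    for p in sorted(root.rglob("*")):
        if any(s in p.resolve().parents or p.resolve() == s for s in skipped):
            continue
        if p.is_file():
            out[str(p.relative_to(root))] = sha256(p)
    return out


def doc(*pairs, dialect="single_line") -> FastaDocument:
    """Build a document from (header, sequence) pairs."""
    return FastaDocument(tuple(FastaRecord(h, s) for h, s in pairs), dialect)
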