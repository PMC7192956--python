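# Methods

## What the package models

`mdop` reimplements, in Python, a small toolkit of nine file- and
sequence-organization operations used to stage DNA-barcode records and
their metadata files (specimen images, AB1 chromatograms, FASTA sequences)
for upload to centralized repositories. There is no statistical model: the
"science" here is a set of exact contracts — discovery, copying,
partitioning, and sequence normalization — and the package's job is to
honor them bit-for-bit, reproducibly, and without ever destroying data.

## Output naming

Every operation derives its output name from a `NamingContext`: run date,
operation token, optional file type, optional folder index. The rendered
form is `YYYYMMDD_<op>[_TYP][_#][.ext]` — eight zero-padded digits, the
operation name verbatim, `JPG`/`AB1`/`FAS` for the three type-parameterized
operations, a 1-based counter for the size-partitioning folders, `.txt` for
the file list and `.fas` for the five sequence outputs. Two deliberate
normalizations: no spaces and no parentheses ever appear in a rendered name
(both are hostile to downstream tooling), and the folder index starts at 1.
The run date defaults to "today" but is injectable through every API layer
and the CLI's `--date` flag, which is what makes full runs reproducible.

If a rendered name already exists at its destination, the operation fails
with an already-exists error rather than overwriting. The original behavior
on collisions is unspecified; failing closed is the data-safe default.

## File operations

**Discovery** (`scan_targets`) matches files by extension,
case-insensitively: `jpg` for JPG, `ab1` for AB1, and exactly `fas` or
`fasta` for FAS (`.fa`/`.fna` deliberately excluded — the toolkit names the
type "FASTA/FAS" and we match that spelling, not every FASTA alias).
Recursive scans walk the whole tree without following symbolic links (cycle
safety); non-recursive scans, used by `max_packs` and `copy_by_list`, look
only at the directory itself. Results are ordered lexicographically by full
path, so a given tree always scans to the same list — this ordering is what
makes packing deterministic.

**`recursive_copy`** creates its output folder first (claiming the name),
then scans the tree with that folder excluded, so a run never re-copies its
own output. Files from different subdirectories that share a base name are
kept by suffixing the later copies `_1`, `_2`, … before the extension, with
a warning logged; silent overwrite would lose data. Copies preserve bytes
and timestamps (`shutil.copy2`).

**`plan_packs` / `execute_packs`** split a file list into folders whose
byte sums respect a cap. The algorithm is sequential next-fit in scan
order: append each file to the current folder unless it would exceed the
cap, then open the next. This is not optimal bin-packing — it can use more
folders than the minimum — but it is reproducible, order-stable, and
matches how a person fills upload batches. A single file larger than the
cap can never fit and raises an error naming the file. The CLI's
`--max-size` is interpreted as MB (10^6 bytes), the unit upload limits are
usually quoted in; the library layer works in bytes.

**`copy_by_list`** parses a one-name-per-line text file tolerantly (LF or
CRLF, optional trailing blank line, padding trimmed; a file with no usable
lines is an error), de-duplicates repeated names with a warning, copies the
matches found in the top level of the source directory only, and returns
the sorted list of names with no match. Missing names are reported, not
fatal: curation lists routinely reference files that were already culled.

## Sequence operations

FASTA is parsed by a small dedicated reader rather than a general
bioinformatics library because the toolkit's contracts are about the *file
dialect* — it must distinguish single-line from wrapped (multi-line)
records, which mainstream parsers deliberately abstract away. The reader
tolerates a UTF-8 BOM, leading blank lines, and blank interior lines
(skipped with a warning); it rejects non-FASTA content, empty headers,
empty sequences, and `>` inside a sequence line. Headers keep everything
after `>` verbatim except trailing whitespace, which is invisible in a file
and would make header equality ill-defined. Writing always emits
`>header\nsequence\n` with LF endings, so write∘read is the identity on
documents and read∘write normalizes wrapping only.

- **degap** deletes `-` characters only; `.` and `~` are left untouched
  (they are not this toolkit's gap convention). A record that is entirely
  gaps raises an error naming the header — an empty sequence is not
  uploadable, and silently dropping the record would hide a data problem.
- **rank_seq** is a stable sort by sequence length, shortest first; ties
  keep input order, never reordering by header.
- **head_derep** keeps the *first* record for each distinct header, in
  first-seen order. First-occurrence survival is a choice (the convention
  leaves it open); it is deterministic and preserves file order. Headers
  are compared whole — specimen-ID headers carry meaningful pipes and
  spaces, so no tokenization at the first space.
- **seq_derep** keeps the first record per distinct sequence, keyed
  case-insensitively: soft-masked lowercase is a formatting artifact, not a
  haplotype difference. Gap characters are *not* stripped before keying —
  run `degap` first if aligned duplicates should collapse. The output
  record count is the file's distinct-sequence (haplotype) count.
- **multi_to_single_fasta** is read → write-single-line under the
  convention name; record count, headers, and concatenated sequences are
  unchanged.

The four in-place transforms conventionally require single-line input; the
CLI enforces this (a multi-line file is rejected with a pointer to
`multi_to_single_fasta`), while the library functions operate on parsed
documents regardless of dialect, since parsing has already normalized the
wrapping.

## Command-line interface

Each operation is a subcommand with two entry modes: flags, or — when
required flags are missing *and* stdin is a TTY — interactive prompts in a
fixed order (path, then file type where applicable, then the size cap).
Prompting is disabled for non-TTY stdin so the tool stays scriptable; both
modes funnel into the same library calls, so they produce byte-identical
outputs for the same effective parameters. Exit codes: 0 with created paths
on stdout; 1 with a one-line diagnostic on stderr for operation errors;
2 for usage errors. `--log-file` appends a timestamped audit line per run
(submission work benefits from a trail); the handler is attached per run
and removed afterwards.

## Synthetic data

All tests and the acceptance script run on generated inputs
(`mdop.fixtures`), pure functions of their spec and seed.

*Trees* (`TreeSpec`): a random directory tree (default depth 2, 1–3
subdirectories per level, 0–4 files per directory) populated with JPG /
AB1 / FAS / decoy files in configurable proportions, random sizes (default
16–256 bytes — content never matters, only bytes and counts), mixed-case
extensions, and an optional duplicate-base-name rate to exercise collision
handling. JPG and AB1 payloads are opaque random bytes; this is faithful,
not a shortcut, because no operation ever opens them. The returned manifest
(paths, sizes, per-type counts) is the oracle for discovery, copying and
packing tests.

*FASTA* (`FastaSpec`): per-position gap *insertions* with probability
`gap_fraction` (so the inserted-gap count is exact ground truth for degap,
and a gap-only record cannot arise), duplicate-header and
duplicate-sequence rates that reuse an earlier record's header/sequence
verbatim (optionally case-swapped under `lowercase_rate`, so duplicates
still share a case-insensitive key), and a wrap width (0 = single-line,
80 = classic wrapped layout). Distinct-header and distinct-sequence-key
counts are tallied over the records as written.

What the generators do *not* emulate: real chromatogram or image content,
biologically plausible sequence composition, IUPAC ambiguity codes, very
large files, or pathological filesystems (permissions, non-UTF-8 names).
Passing tests therefore demonstrate the organizational contracts — exact
discovery, conservation under copying, cap-respecting partitions, exact
transform semantics — not robustness to every real-world filesystem or
sequencing artifact.

## Verification strategy and problem sizes

Every operation is tested against an independent oracle: a hand-rolled
brute-force tree walk (restated extension table, no shared code) for
discovery; SHA-256 checksums for conservation; hand-simulated packing and
hypothesis property tests for the partition invariants; Biopython's parser
as an independent cross-check of FASTA reading; and the generators' ground
truth for the transforms. The acceptance checks fuzz 100 seeded trees for
discovery, 40 for copy conservation, 100 size lists for packing, 100 FASTA
fixtures for round-tripping, and 20 for transform ground truth — sizes
chosen so the whole suite stays at desk scale (a couple of seconds) while
each property sees a broad sample of shapes.

## Known limitations

- Extension-based typing only: a mislabeled file is trusted.
- Next-fit packing can exceed the optimal folder count.
- `recursive_copy` on a later date treats a previous run's output folder as
  ordinary source data (only its *own* output is excluded); re-runs on the
  same date are blocked by the collision error.
- Nucleotide semantics are not validated: any non-whitespace, non-`>`
  sequence characters are accepted and preserved.
- Interactive prompts require a real TTY; there is no `--interactive`
  override.
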