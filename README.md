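# mdop

Organize DNA-barcode files and sequences for upload to centralized
repositories such as BOLD (Barcode of Life Datasystems).

DNA-barcode submissions bundle far more than sequences: specimen images
(JPG), Sanger chromatogram traces (AB1), and multiple-sequence FASTA files
accumulate across nested project folders, research groups, and years.
Repositories want them flat, uniquely named, size-capped per upload, gap-free,
and de-duplicated. `mdop` provides the nine small operations that get a
project tree from "how it grew" to "what the upload form wants" — as plain
Python functions and as an `mdop` shell command — for taxonomists, sequencing
technicians, and data managers who would otherwise do this by hand (or be
blocked from a terminal entirely on secured networks).

## The nine operations

File organization (`mdop.fsops`):

| operation | what it does |
|---|---|
| `target_file_list` | list every JPG / AB1 / FAS file in a tree into a text manifest |
| `recursive_copy` | copy all matching files from a tree into one new folder |
| `max_packs` | partition a folder's files into size-capped upload folders |
| `copy_by_list` | copy exactly the files named in a one-per-line list file |

Sequence preparation (`mdop.fasta`), operating on single-line FASTA:

| operation | what it does |
|---|---|
| `degap` | delete alignment gaps (`-`) so unaligned sequences are uploaded |
| `rank_seq` | sort records shortest → longest for length screening |
| `head_derep` | keep one record per distinct header |
| `seq_derep` | keep one record per distinct sequence (haplotype count) |
| `multi_to_single_fasta` | flatten wrapped (multi-line) FASTA to single-line |

Every output is stamped `YYYYMMDD_<operation>[_TYP][_#]`, e.g.
`20200423_target_file_list_JPG.txt`, `20200423_max_packs_AB1_1`,
`20200423_degap.fas`. Nothing is ever overwritten or moved: an existing
output name aborts the run, and sources are only read.

## Worked example

Starting from a project tree holding two images and two traces, plus a
wrapped three-record `barcodes.fas` in which all three records spell the
same COI sequence (one wrapped across two lines, one soft-masked in
lowercase):

```sh
$ mdop target_file_list --dir ./project --type JPG --date 20200423
project/20200423_target_file_list_JPG.txt

$ mdop recursive_copy --dir ./project --type AB1 --date 20200423
/tmp/demo/project/20200423_recursive_copy_AB1

$ mdop multi_to_single_fasta --in barcodes.fas --out-dir . --date 20200423
20200423_multi_to_single_fasta.fas

$ mdop seq_derep --in 20200423_multi_to_single_fasta.fas --out-dir . --date 20200423
20200423_seq_derep.fas

$ wc -l < 20200423_seq_derep.fas
2
```

Each command prints the path it created and exits 0; errors print a
one-line diagnostic and exit 1 (usage problems exit 2). The list file
holds one `path<TAB>name` line per image found; the copy folder holds both
traces. The final file has two lines — one header plus one sequence: the
three records collapse to a single haplotype, because sequences are
compared case-insensitively and the wrapped record was flattened before
dereplication.

Run any subcommand without flags in a terminal and it prompts for the
missing pieces instead (path first, then file type, then the size cap for
`max_packs`); prompting is disabled when stdin is not a TTY, so scripts
fail fast rather than hang. `--date` pins the date stamp for reproducible
runs; `--log-file` appends an audit line per run.

The same operations are ordinary functions:

```python
import mdop

doc = mdop.read_fasta("barcodes.fas")
print(len(doc), len(mdop.seq_derep(doc)))   # e.g. "200 143" — records, haplotypes
plan = mdop.plan_packs(mdop.scan_targets("imgs", "JPG", recursive=False), 10**8)
```

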