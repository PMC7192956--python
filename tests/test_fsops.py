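"""File discovery, listing, copying, packing, and list-driven subsetting."""

import datetime
import os

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import checksum_tree, oracle_walk, sha256
from mdop import fsops
from mdop.errors import (
    AlreadyExistsError,
    EmptyListError,
    InputPathError,
    OversizeFileError,
)
from mdop.fixtures import TreeSpec, generate_tree
from mdop.fsops import FileEntry, TargetFileType

D = datetime.date(2020, 4, 23)


def entry(tmp_path, name, size):
    p = tmp_path / name
    p.write_bytes(b"x" * size)
    return FileEntry.from_path(p)


class TestTargetFileType:
    @pytest.mark.parametrize(
        ("ftype", "name", "expected"),
        [
            ("JPG", "a.jpg", True),
            ("JPG", "a.JPG", True),
            ("JPG", "a.jpeg", False),
            ("AB1", "trace.ab1", True),
            ("AB1", "trace.AB1", True),
            ("FAS", "s.fas", True),
            ("FAS", "s.fasta", True),
            ("FAS", "s.FASTA", True),
            ("FAS", "s.fa", False),  # only the two named spellings count
            ("FAS", "s.fna", False),
            ("JPG", "noext", False),
        ],
    )
    def test_extension_matching(self, ftype, name, expected):
        assert TargetFileType.coerce(ftype).matches(name) is expected

    def test_coerce_rejects_unknown(self):
        with pytest.raises(ValueError):
            TargetFileType.coerce("PNG")


class TestScanTargets:
    def test_recursive_matches_oracle_on_mixed_tree(self, tmp_path):
        (tmp_path / "a" / "b").mkdir(parents=True)
        (tmp_path / "a" / "x.jpg").write_bytes(b"1")
        (tmp_path / "a" / "b" / "y.JPG").write_bytes(b"2")
        (tmp_path / "a" / "b" / "z.ab1").write_bytes(b"3")
        got = fsops.scan_targets(tmp_path, "JPG", recursive=True)
        assert [e.absolute_path for e in got] == oracle_walk(tmp_path, "JPG")
        assert [e.base_name for e in got] == ["y.JPG", "x.jpg"] or [
            e.base_name for e in got
        ] == ["x.jpg", "y.JPG"]

    def test_empty_directory_yields_nothing(self, tmp_path):
        for ftype in TargetFileType:
            assert fsops.scan_targets(tmp_path, ftype) == []

    def test_non_recursive_ignores_subdirectories(self, tmp_path):
        (tmp_path / "sub").mkdir()
        (tmp_path / "x.fas").write_bytes(b"1")
        (tmp_path / "sub" / "y.fas").write_bytes(b"2")
        got = fsops.scan_targets(tmp_path, "FAS", recursive=False)
        assert [e.base_name for e in got] == ["x.fas"]

    def test_symlinked_directories_not_followed(self, tmp_path):
        real = tmp_path / "real"
        real.mkdir()
        (real / "x.jpg").write_bytes(b"1")
        os.symlink(real, tmp_path / "loop")
        got = fsops.scan_targets(tmp_path, "JPG", recursive=True)
        assert len(got) == 1

    def test_missing_root_raises(self, tmp_path):
        with pytest.raises(InputPathError):
            fsops.scan_targets(tmp_path / "nope", "JPG")

    @pytest.mark.parametrize("seed", range(5))
    def test_fuzzed_trees_match_oracle(self, tmp_path, seed):
        spec = TreeSpec(depth=2, files_per_dir=(0, 4), seed=seed)
        generate_tree(spec, tmp_path)
        for ftype in ("JPG", "AB1", "FAS"):
            got = [e.absolute_path for e in fsops.scan_targets(tmp_path, ftype)]
            assert got == oracle_walk(tmp_path, ftype)
            flat = [
                e.absolute_path
                for e in fsops.scan_targets(tmp_path, ftype, recursive=False)
            ]
            assert flat == oracle_walk(tmp_path, ftype, recursive=False)


class TestWriteFileList:
    def test_empty_entries_give_empty_file_with_convention_name(self, tmp_path):
        out = fsops.write_file_list([], tmp_path, "JPG", D)
        assert out.name == "20200423_target_file_list_JPG.txt"
        assert out.read_text() == ""

    def test_lines_mirror_entries_in_order(self, tmp_path):
        entries = [entry(tmp_path, f"s{i}.jpg", 4) for i in range(3)]
        out = fsops.write_file_list(entries, tmp_path, "JPG", D)
        lines = out.read_text().splitlines()
        assert lines == [
            f"{e.absolute_path}\t{e.base_name}" for e in entries
        ]

    def test_collision_refused(self, tmp_path):
        fsops.write_file_list([], tmp_path, "JPG", D)
        with pytest.raises(AlreadyExistsError):
            fsops.write_file_list([], tmp_path, "JPG", D)


class TestRecursiveCopy:
    def test_copies_nested_files_byte_identically(self, tmp_path):
        deep = tmp_path / "a" / "deep" / "nested"
        deep.mkdir(parents=True)
        (tmp_path / "a" / "s1.ab1").write_bytes(b"trace-one")
        (deep / "s2.ab1").write_bytes(b"trace-two")
        before = checksum_tree(tmp_path)
        out = fsops.recursive_copy(tmp_path, "AB1", D)
        assert out.name == "20200423_recursive_copy_AB1"
        assert sorted(p.name for p in out.iterdir()) == ["s1.ab1", "s2.ab1"]
        assert sha256(out / "s1.ab1") == sha256(tmp_path / "a" / "s1.ab1")
        assert sha256(out / "s2.ab1") == sha256(deep / "s2.ab1")
        # sources untouched
        assert checksum_tree(tmp_path, skip_under=[out]) == before

    def test_no_matches_creates_empty_folder(self, tmp_path):
        out = fsops.recursive_copy(tmp_path, "JPG", D)
        assert out.is_dir() and list(out.iterdir()) == []

    def test_base_name_collision_renamed_not_lost(self, tmp_path):
        for sub in ("x", "y"):
            (tmp_path / sub).mkdir()
            (tmp_path / sub / "s.jpg").write_bytes(sub.encode())
        out = fsops.recursive_copy(tmp_path, "JPG", D)
        copies = sorted(p.name for p in out.iterdir())
        assert copies == ["s.jpg", "s_1.jpg"]
        assert {p.read_bytes() for p in out.iterdir()} == {b"x", b"y"}

    def test_rerun_same_date_refused(self, tmp_path):
        fsops.recursive_copy(tmp_path, "JPG", D)
        with pytest.raises(AlreadyExistsError):
            fsops.recursive_copy(tmp_path, "JPG", D)

    def test_output_folder_excluded_from_own_scan(self, tmp_path):
        (tmp_path / "s.jpg").write_bytes(b"photo")
        out = fsops.recursive_copy(tmp_path, "JPG", D)
        # exactly one copy: the output folder's own content was not rescanned
        assert [p.name for p in out.iterdir()] == ["s.jpg"]


class TestPlanPacks:
    def test_sequential_fill_matches_hand_simulation(self, tmp_path):
        entries = [entry(tmp_path, f"f{i}.jpg", 40) for i in range(3)]
        plan = fsops.plan_packs(entries, 100)
        assert [[e.size_bytes for e in pack] for pack in plan.packs] == [[40, 40], [40]]

    def test_single_file_single_pack(self, tmp_path):
        plan = fsops.plan_packs([entry(tmp_path, "f.jpg", 10)], 100)
        assert [[e.size_bytes for e in p] for p in plan.packs] == [[10]]

    def test_oversize_file_raises_naming_the_file(self, tmp_path):
        big = entry(tmp_path, "huge.jpg", 150)
        with pytest.raises(OversizeFileError, match="huge.jpg"):
            fsops.plan_packs([big], 100)

    @settings(max_examples=60, deadline=None)
    @given(sizes=st.lists(st.integers(1, 100), max_size=50))
    def test_partition_invariants(self, sizes):
        """Every pack within cap; packs partition the input in order."""
        cap = 100
        entries = [FileEntry(f"/v/f{i}", f"f{i}", s) for i, s in enumerate(sizes)]
        plan = fsops.plan_packs(entries, cap)
        flat = [e for pack in plan.packs for e in pack]
        assert flat == entries
        assert all(sum(e.size_bytes for e in pack) <= cap for pack in plan.packs)
        assert all(pack for pack in plan.packs)


class TestExecutePacks:
    def test_folders_named_and_filled_in_index_order(self, tmp_path):
        src = tmp_path / "src"
        src.mkdir()
        entries = [entry(src, f"f{i}.jpg", 40) for i in range(3)]
        plan = fsops.plan_packs(entries, 100)
        folders = fsops.execute_packs(plan, tmp_path, "JPG", D)
        assert [f.name for f in folders] == [
            "20200423_max_packs_JPG_1",
            "20200423_max_packs_JPG_2",
        ]
        sums = [
            sum(p.stat().st_size for p in f.iterdir()) for f in folders
        ]
        assert all(s <= 100 for s in sums)
        assert sum(len(list(f.iterdir())) for f in folders) == 3

    def test_empty_plan_creates_nothing(self, tmp_path):
        plan = fsops.plan_packs([], 100)
        assert fsops.execute_packs(plan, tmp_path, "JPG", D) == []
        assert list(tmp_path.iterdir()) == []

    def test_collision_refused(self, tmp_path):
        (tmp_path / "20200423_max_packs_JPG_1").mkdir()
        plan = fsops.plan_packs([entry(tmp_path, "f.jpg", 1)], 10)
        with pytest.raises(AlreadyExistsError):
            fsops.execute_packs(plan, tmp_path, "JPG", D)


class TestParseFileList:
    @pytest.mark.parametrize(
        ("content", "expected"),
        [
            ("s1.jpg\ns2.jpg\n\n", ["s1.jpg", "s2.jpg"]),  # trailing blank line
            ("s1.jpg", ["s1.jpg"]),  # no trailing newline
            ("s1.jpg\r\ns2.jpg\r\n\r\n", ["s1.jpg", "s2.jpg"]),  # CRLF
            ("  s1.jpg \ns2.jpg\n", ["s1.jpg", "s2.jpg"]),  # padding trimmed
            ("a.jpg\na.jpg\n", ["a.jpg", "a.jpg"]),  # duplicates preserved here
        ],
    )
    def test_tolerant_line_parsing(self, tmp_path, content, expected):
        f = tmp_path / "list.txt"
        f.write_text(content)
        assert fsops.parse_file_list(f) == expected

    def test_blank_only_file_raises(self, tmp_path):
        f = tmp_path / "list.txt"
        f.write_text("\n\n\n")
        with pytest.raises(EmptyListError):
            fsops.parse_file_list(f)

    def test_missing_file_raises(self, tmp_path):
        with pytest.raises(InputPathError):
            fsops.parse_file_list(tmp_path / "nope.txt")


class TestCopyByList:
    def test_copies_exactly_the_intersection(self, tmp_path):
        for n in ("s1.jpg", "s2.jpg", "s3.jpg"):
            (tmp_path / n).write_bytes(n.encode())
        out, missing = fsops.copy_by_list(tmp_path, ["s1.jpg", "s3.jpg"], D)
        assert out.name == "20200423_copy_by_list"
        assert sorted(p.name for p in out.iterdir()) == ["s1.jpg", "s3.jpg"]
        assert missing == []

    def test_absent_names_reported_not_fatal(self, tmp_path):
        out, missing = fsops.copy_by_list(tmp_path, ["absent.jpg"], D)
        assert list(out.iterdir()) == []
        assert missing == ["absent.jpg"]

    def test_subdirectories_never_searched(self, tmp_path):
        (tmp_path / "s1.jpg").write_bytes(b"1")
        sub = tmp_path / "sub"
        sub.mkdir()
        (sub / "s2.jpg").write_bytes(b"2")
        out, missing = fsops.copy_by_list(tmp_path, ["s2.jpg"], D)
        assert list(out.iterdir()) == []
        assert missing == ["s2.jpg"]

    def test_duplicate_requests_copied_once(self, tmp_path):
        (tmp_path / "s1.jpg").write_bytes(b"1")
        out, missing = fsops.copy_by_list(tmp_path, ["s1.jpg", "s1.jpg"], D)
        assert [p.name for p in out.iterdir()] == ["s1.jpg"]
        assert missing == []

    def test_request_is_covered_by_copied_plus_missing(self, tmp_path):
        present = [f"s{i}.jpg" for i in range(4)]
        for n in present:
            (tmp_path / n).write_bytes(b"x")
        asked = present[:2] + ["ghost1.jpg", "ghost2.jpg"]
        out, missing = fsops.copy_by_list(tmp_path, asked, D)
        copied = {p.name for p in out.iterdir()}
        assert copied | set(missing) == set(asked)
        assert copied.isdisjoint(missing)
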