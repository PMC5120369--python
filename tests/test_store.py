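"""Overlap store: BED parsing, interval merging, containment, persistence."""

import sqlite3

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import dmpenrich as dm
from dmpenrich.errors import BedParseError, ManifestError, StoreError


def _write(path, text):
    path.write_text(text)
    return path


class TestReadBed:
    def test_single_record(self, tmp_path):
        path = _write(tmp_path / "a.bed", "chr1\t100\t200\n")
        assert dm.read_bed(path) == [("chr1", 100, 200)]

    def test_extra_columns_ignored_and_file_order_kept(self, tmp_path):
        path = _write(tmp_path / "a.bed",
                      "chr2\t50\t60\tpeak1\t900\nchr1\t10\t20\nchr1\t0\t5\n")
        assert dm.read_bed(path) == [("chr2", 50, 60), ("chr1", 10, 20),
                                     ("chr1", 0, 5)]

    def test_empty_file_is_empty_list(self, tmp_path):
        assert dm.read_bed(_write(tmp_path / "a.bed", "")) == []

    @pytest.mark.parametrize("line,what", [
        ("chr1\t200\t200", "zero-length"),
        ("chr1\t300\t200", "negative-length"),
        ("chr1\tx\t200", "non-integer"),
        ("chr1\t100", "too few fields"),
        ("1\t100\t200", "missing chr prefix"),
    ])
    def test_malformed_lines_raise_with_line_number(self, tmp_path, line, what):
        path = _write(tmp_path / "bad.bed", "chr1\t0\t10\n" + line + "\n")
        with pytest.raises(BedParseError, match="line 2"):
            dm.read_bed(path)

    def test_gzip_transparent(self, tmp_path):
        import gzip
        path = tmp_path / "a.bed.gz"
        with gzip.open(path, "wt") as fh:
            fh.write("chr1\t5\t9\n")
        assert dm.read_bed(path) == [("chr1", 5, 9)]


class TestMergeIntervals:
    def test_overlap_coalesce(self):
        assert dm.merge_intervals([("chr1", 0, 10), ("chr1", 5, 20)]) == \
            [("chr1", 0, 20)]

    def test_abutting_coalesce(self):
        assert dm.merge_intervals([("chr1", 0, 10), ("chr1", 10, 20)]) == \
            [("chr1", 0, 20)]

    def test_cross_chromosome_independence(self):
        assert dm.merge_intervals([("chr2", 0, 10), ("chr1", 0, 10)]) == \
            [("chr1", 0, 10), ("chr2", 0, 10)]

    def test_empty(self):
        assert dm.merge_intervals([]) == []

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.lists(st.tuples(st.integers(0, 9_900), st.integers(1, 100)),
                    max_size=100))
    def test_union_matches_per_base_oracle(self, raw):
        """Merged coverage equals a brute-force per-base union on a 10 kb toy chromosome."""
        intervals = [("chrT", s, s + w) for s, w in raw]
        merged = dm.merge_intervals(intervals)
        covered = np.zeros(10_000, dtype=bool)
        for _, s, e in intervals:
            covered[s:e] = True
        oracle = np.zeros(10_000, dtype=bool)
        for _, s, e in merged:
            oracle[s:e] = True
        assert np.array_equal(covered, oracle)
        # sorted, non-overlapping, non-abutting
        for (c1, s1, e1), (c2, s2, e2) in zip(merged, merged[1:]):
            assert (c1, s1) <= (c2, s2)
            assert c1 != c2 or s2 > e1


def _oracle_matrix(manifest, tracks):
    """Quadratic all-pairs containment check."""
    bits = np.zeros((len(manifest), len(tracks)), dtype=bool)
    for i, (chrom, pos) in enumerate(zip(manifest["chrom"], manifest["pos"])):
        for j, track in enumerate(tracks):
            bits[i, j] = any(c == chrom and s <= pos - 1 < e
                             for c, s, e in track.intervals)
    return bits


class TestOverlapMatrix:
    def test_interior_point_hits(self, tiny_manifest):
        track = dm.HotspotTrack.make("s1", [("chr1", 100, 200)])
        mat = dm.build_overlap_matrix(tiny_manifest, [track])
        # cg01 at 1-based 150? no: cg01 pos=100 -> 0-based 99, outside [100,200)
        assert mat.bits[0, 0] == False  # noqa: E712  left-boundary convention
        track2 = dm.HotspotTrack.make("s2", [("chr1", 99, 200)])
        mat2 = dm.build_overlap_matrix(tiny_manifest, [track2])
        assert mat2.bits[0, 0] == True  # noqa: E712

    def test_left_boundary_convention(self, tiny_manifest):
        # probe at 1-based 150 vs interval starting at 150: 0-based 149 misses
        track = dm.HotspotTrack.make("s1", [("chr3", 150, 400)])
        mat = dm.build_overlap_matrix(tiny_manifest, [track])
        assert not mat.bits[5, 0]
        track = dm.HotspotTrack.make("s1", [("chr3", 149, 400)])
        assert dm.build_overlap_matrix(tiny_manifest, [track]).bits[5, 0]

    def test_absent_chromosome_gives_zero_row(self, tiny_manifest):
        track = dm.HotspotTrack.make("s1", [("chr9", 0, 10_000)])
        mat = dm.build_overlap_matrix(tiny_manifest, [track])
        assert not mat.bits.any()

    def test_matches_quadratic_oracle_on_random_instance(self, toy_study):
        rng = np.random.default_rng(7)
        manifest = toy_study["manifest"].sample(n=200, random_state=3)
        tracks = []
        for j in range(5):
            raw = [("chr%d" % rng.integers(1, 4), int(s), int(s) + int(w))
                   for s, w in zip(rng.integers(0, 1_999_000, 60),
                                   rng.integers(1, 800, 60))]
            tracks.append(dm.HotspotTrack.make(f"t{j}", raw))
        mat = dm.build_overlap_matrix(manifest, tracks)
        assert np.array_equal(mat.bits, _oracle_matrix(manifest, tracks))

    def test_bed_round_trip_of_probe_coordinates(self, tmp_path, tiny_manifest):
        """A probe emitted as (pos-1, pos) and re-imported maps to the same row."""
        bed = tmp_path / "probes.bed"
        bed.write_text("".join(f"{c}\t{p - 1}\t{p}\n" for c, p in
                               zip(tiny_manifest["chrom"], tiny_manifest["pos"])))
        ids, missing = dm.resolve_input(bed, tiny_manifest, fmt="bed")
        assert ids == list(tiny_manifest["probe_id"]) and missing == []


@pytest.fixture()
def small_matrix(toy_study):
    mat = toy_study["matrix"]
    return dm.OverlapMatrix(mat.probe_ids[:10], mat.sample_ids[:3],
                            mat.bits[:10, :3])


class TestPersistence:
    def test_round_trip_bit_exact(self, tmp_path, small_matrix, toy_study):
        meta = toy_study["metadata"].iloc[:3]
        path = tmp_path / "store.db"
        dm.persist_store(small_matrix, meta, path, dataset="dnase")
        loaded, meta2 = dm.load_store(path)
        assert loaded.probe_ids == small_matrix.probe_ids
        assert loaded.sample_ids == small_matrix.sample_ids
        assert np.array_equal(loaded.bits, small_matrix.bits)
        assert list(meta2["dataset"]) == ["dnase"] * 3
        assert meta2[list(dm.store.METADATA_COLUMNS)].equals(
            meta.reset_index(drop=True))

    def test_append_leaves_existing_panel_untouched(self, tmp_path, toy_study):
        mat = toy_study["matrix"]
        meta = toy_study["metadata"]
        first = dm.OverlapMatrix(mat.probe_ids, mat.sample_ids[:3],
                                 mat.bits[:, :3])
        second = dm.OverlapMatrix(mat.probe_ids, mat.sample_ids[3:5],
                                  mat.bits[:, 3:5])
        path = tmp_path / "store.db"
        dm.persist_store(first, meta.iloc[:3], path, dataset="a")
        dm.persist_store(second, meta.iloc[3:5], path, dataset="b", append=True)
        assert dm.store_datasets(path) == ["a", "b"]
        loaded, meta2 = dm.load_store(path)
        assert len(loaded.sample_ids) == 5
        assert np.array_equal(loaded.bits[:, :3], first.bits)
        only_a, _ = dm.load_store(path, datasets=["a"])
        assert np.array_equal(only_a.bits, first.bits)

    def test_append_rejects_probe_mismatch_and_duplicate_dataset(
            self, tmp_path, small_matrix, toy_study):
        meta = toy_study["metadata"].iloc[:3]
        path = tmp_path / "store.db"
        dm.persist_store(small_matrix, meta, path, dataset="a")
        with pytest.raises(StoreError, match="already in store"):
            dm.persist_store(small_matrix, meta, path, dataset="a", append=True)
        other = dm.OverlapMatrix(["cgX"], small_matrix.sample_ids,
                                 np.zeros((1, 3), bool))
        with pytest.raises(StoreError, match="probe universe"):
            dm.persist_store(other, meta, path, dataset="b", append=True)

    def test_truncated_store_errors_not_silent(self, tmp_path, small_matrix,
                                               toy_study):
        path = tmp_path / "store.db"
        dm.persist_store(small_matrix, toy_study["metadata"].iloc[:3], path)
        data = path.read_bytes()
        path.write_bytes(data[:-1])
        with pytest.raises(StoreError):
            dm.load_store(path)

    def test_version_mismatch_errors(self, tmp_path, small_matrix, toy_study):
        path = tmp_path / "store.db"
        dm.persist_store(small_matrix, toy_study["metadata"].iloc[:3], path)
        con = sqlite3.connect(path)
        con.execute("UPDATE store_info SET value='99' WHERE key='format_version'")
        con.commit()
        con.close()
        with pytest.raises(StoreError, match="format version"):
            dm.load_store(path)


class TestManifestReader:
    def test_reads_and_normalizes(self, tmp_path):
        path = tmp_path / "man.tsv"
        path.write_text(
            "IlmnID\tCHR\tMAPINFO\tUCSC_RefGene_Group\tRelation_to_UCSC_CpG_Island\n"
            "cg1\tchr1\t100\tBody;TSS200\tN_Shore\n"
            "cg2\tchr2\t5\t\t\n"
            "cg3\tchr2\t50\t3'UTR\tIsland\n")
        df = dm.read_manifest(path)
        assert list(df["gene_group"]) == ["Body", "IGR", "3UTR"]
        assert list(df["cpg_relation"]) == ["N_Shore", "OpenSea", "Island"]

    def test_rejects_bare_chromosome_names(self, tmp_path):
        path = tmp_path / "man.tsv"
        path.write_text("probe_id\tchrom\tpos\tgene_group\tcpg_relation\n"
                        "cg1\t1\t100\tBody\tIsland\n")
        with pytest.raises(ManifestError, match="chr"):
            dm.read_manifest(path)

    def test_rejects_duplicates_and_bad_positions(self, tmp_path):
        dup = tmp_path / "dup.tsv"
        dup.write_text("probe_id\tchrom\tpos\tgene_group\tcpg_relation\n"
                       "cg1\tchr1\t100\tBody\tIsland\n"
                       "cg1\tchr1\t200\tBody\tIsland\n")
        with pytest.raises(ManifestError, match="duplicate"):
            dm.read_manifest(dup)
        zero = tmp_path / "zero.tsv"
        zero.write_text("probe_id\tchrom\tpos\tgene_group\tcpg_relation\n"
                        "cg1\tchr1\t0\tBody\tIsland\n")
        with pytest.raises(ManifestError, match=">= 1"):
            dm.read_manifest(zero)
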