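"""Genome/track/dataset I/O and dMean normalization."""

import numpy as np
import pytest

from hdgsnet import genome_io as gio


@pytest.fixture
def tmp_write(tmp_path):
    def _write(name, text):
        p = tmp_path / name
        p.write_text(text)
        return str(p)
    return _write


class TestFasta:
    def test_case_normalization(self, tmp_write):
        path = tmp_write("a.fa", ">c1\nacgt\n")
        (rec,) = gio.read_fasta(path)
        assert (rec.chrom, rec.seq) == ("c1", "ACGT")

    def test_multi_record_lengths(self, tmp_write):
        recs = gio.read_fasta(tmp_write("b.fa", ">c1\nACGT\n>c2\nTT\n"))
        assert [(r.chrom, len(r)) for r in recs] == [("c1", 4), ("c2", 2)]

    def test_missing_header_is_parse_error(self, tmp_write):
        with pytest.raises(gio.ParseError, match="header"):
            gio.read_fasta(tmp_write("c.fa", "ACGT\n"))

    def test_empty_file_is_parse_error(self, tmp_write):
        with pytest.raises(gio.ParseError):
            gio.read_fasta(tmp_write("d.fa", ""))

    def test_unknown_symbols_become_n(self, tmp_write):
        (rec,) = gio.read_fasta(tmp_write("e.fa", ">c1\nAC-RT\n"))
        assert rec.seq == "ACNNT"

    def test_roundtrip(self, tmp_path, tmp_write):
        recs = gio.read_fasta(tmp_write("f.fa", ">c1\nACGTACGT\n>c2\nGGCC\n"))
        out = str(tmp_path / "out.fa")
        gio.write_fasta(recs, out, width=3)
        again = gio.read_fasta(out)
        assert [(r.chrom, r.seq) for r in again] == \
            [(r.chrom, r.seq) for r in recs]


class TestOccupancyTracks:
    def test_bedgraph_interval_expansion(self, tmp_write):
        (t,) = gio.read_occupancy(tmp_write("t.bg", "c1\t0\t3\t2.0\n"))
        assert np.allclose(t.values, [2.0, 2.0, 2.0])
        assert t.covered.all() and not t.normalized

    def test_fixedstep_is_one_based(self, tmp_write):
        (t,) = gio.read_occupancy(
            tmp_write("t.wig", "fixedStep chrom=c1 start=1 step=1\n1\n2\n"),
            format="wig_fixedstep")
        assert np.allclose(t.values, [1.0, 2.0])

    def test_wig_position_offset_property(self, tmp_write):
        # a value at 1-based WIG position p lands at 0-based index p-1
        (t,) = gio.read_occupancy(
            tmp_write("o.wig", "fixedStep chrom=c1 start=5 step=1\n9.0\n"),
            format="wig_fixedstep")
        assert t.values[4] == 9.0 and not t.covered[:4].any()

    def test_reversed_interval_is_error(self, tmp_write):
        with pytest.raises(gio.ParseError, match="end"):
            gio.read_occupancy(tmp_write("bad.bg", "c1\t2\t1\t5.0\n"))

    def test_overlap_is_error(self, tmp_write):
        with pytest.raises(gio.ParseError, match="overlap"):
            gio.read_occupancy(
                tmp_write("ov.bg", "c1\t0\t5\t1.0\nc1\t3\t6\t2.0\n"))

    def test_negative_value_is_error(self, tmp_write):
        with pytest.raises(gio.ParseError, match="negative"):
            gio.read_occupancy(tmp_write("neg.bg", "c1\t0\t2\t-1.0\n"))

    def test_uncovered_gap_reported(self, tmp_write):
        (t,) = gio.read_occupancy(
            tmp_write("gap.bg", "c1\t0\t2\t1.0\nc1\t4\t6\t2.0\n"))
        rep = gio.coverage_report([t])
        assert rep["c1"] == {"length": 6, "covered": 4, "uncovered": 2}
        assert np.allclose(t.values[2:4], 0.0)

    @pytest.mark.parametrize("fmt", ["bedgraph", "wig_fixedstep"])
    def test_write_read_roundtrip(self, fmt, tmp_path):
        rng = np.random.default_rng(0)
        t = gio.OccupancyTrack("c1", rng.random(50))
        path = str(tmp_path / "rt")
        gio.write_occupancy([t], path, format=fmt)
        (back,) = gio.read_occupancy(path, format=fmt)
        assert np.array_equal(back.values, t.values)


class TestDMean:
    def test_single_track(self):
        (t,) = gio.dmean_normalize([gio.OccupancyTrack("c1", [2, 4, 6])])
        assert np.allclose(t.values, [0.5, 1.0, 1.5]) and t.normalized

    def test_mean_is_global_across_tracks(self):
        a, b = gio.dmean_normalize([gio.OccupancyTrack("c1", [1, 1]),
                                    gio.OccupancyTrack("c2", [3, 3])])
        assert np.allclose(a.values, [0.5, 0.5])
        assert np.allclose(b.values, [1.5, 1.5])

    def test_all_zero_is_error(self):
        with pytest.raises(ValueError, match="zero"):
            gio.dmean_normalize([gio.OccupancyTrack("c1", [0, 0, 0])])

    def test_renormalizing_is_guarded(self):
        tracks = gio.dmean_normalize([gio.OccupancyTrack("c1", [1, 2, 3])])
        with pytest.raises(ValueError, match="already"):
            gio.dmean_normalize(tracks)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_output_mean_is_one(self, seed):
        rng = np.random.default_rng(seed)
        tracks = [gio.OccupancyTrack(f"c{i}", rng.gamma(2.0, 1.0, 100))
                  for i in range(3)]
        normed = gio.dmean_normalize(tracks)
        allv = np.concatenate([t.values for t in normed])
        assert abs(allv.mean() - 1.0) < 1e-9


class TestDatasetContainer:
    def _container(self, n):
        rng = np.random.default_rng(42)
        feats = np.zeros((n, 16, 146), dtype=np.uint8)
        feats[:, 0, :] = 1
        return gio.DatasetContainer(
            feats, rng.random(n).astype(np.float32),
            np.array(["c1"] * n, dtype=object),
            np.arange(n, dtype=np.int64), np.array(["+"] * n))

    @pytest.mark.parametrize("n", [5, 0])
    def test_hdf5_roundtrip_bit_identical(self, n, tmp_path):
        c = self._container(n)
        path = str(tmp_path / "d.h5")
        gio.write_dataset(c, path)
        back = gio.read_dataset(path)
        assert np.array_equal(back.features, c.features)
        assert np.array_equal(back.labels, c.labels)
        assert np.array_equal(back.positions, c.positions)
        assert list(back.chroms) == list(c.chroms)
        assert list(back.strands) == list(c.strands)

    def test_missing_labels_is_error(self, tmp_path):
        import h5py
        path = str(tmp_path / "bad.h5")
        with h5py.File(path, "w") as h5:
            h5.create_dataset("features", data=np.zeros((1, 16, 146), dtype="uint8"))
        with pytest.raises(gio.ParseError, match="labels"):
            gio.read_dataset(path)

    def test_length_mismatch_is_error(self):
        with pytest.raises(ValueError, match="length"):
            gio.DatasetContainer(np.zeros((2, 16, 146), dtype=np.uint8),
                                 np.zeros(3, dtype=np.float32),
                                 np.array(["c1"] * 3, dtype=object),
                                 np.zeros(3, dtype=np.int64),
                                 np.array(["+"] * 3))
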