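import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tkde.errors import FormatError, ValidationError
from tkde.peaks_io import (
    BindingSiteCall,
    PeakRecord,
    compute_center,
    read_manifest,
    read_peaks,
    read_sites,
    write_sites,
)

MANIFEST = (
    "dataset_id\tfile_path\tcell_line\treplicate\n"
    "A1\ta1.bed\tA\trep1\n"
    "A2\ta2.bed\tA\trep2\n"
    "B1\tb1.bed\tB\trep1\n"
    "B2\tb2.bed\tB\trep2\n"
)


class TestManifest:
    def test_two_by_two_manifest(self, tmp_path):
        p = tmp_path / "m.tsv"
        p.write_text(MANIFEST)
        m = read_manifest(p)
        assert m.cell_lines == ["A", "B"]
        assert m.datasets_per_cell_line == {"A": 2, "B": 2}
        assert m.entries[0].file_path == tmp_path / "a1.bed"

    def test_duplicate_dataset_id_rejected(self, tmp_path):
        p = tmp_path / "m.tsv"
        p.write_text(MANIFEST + "A1\tother.bed\tC\trep1\n")
        with pytest.raises(ValidationError, match="duplicate"):
            read_manifest(p)

    def test_single_dataset_cell_line_accepted(self, tmp_path):
        p = tmp_path / "m.tsv"
        p.write_text(MANIFEST + "C1\tc1.bed\tC\trep1\n")
        assert read_manifest(p).datasets_per_cell_line["C"] == 1

    @pytest.mark.parametrize("content", ["", "dataset_id\tfile_path\tcell_line\treplicate\n"])
    def test_empty_manifest_rejected(self, tmp_path, content):
        p = tmp_path / "m.tsv"
        p.write_text(content)
        with pytest.raises(ValidationError):
            read_manifest(p)

    def test_missing_column_is_format_error(self, tmp_path):
        p = tmp_path / "m.tsv"
        p.write_text("dataset_id\tfile_path\tcell_line\nA1\ta.bed\tA\n")
        with pytest.raises(FormatError, match="replicate"):
            read_manifest(p)


class TestReadPeaks:
    def test_bed3_line(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chr1\t100\t300\tpk1\t500\t.\n")
        (rec,) = read_peaks(p, "ds")
        assert (rec.chrom, rec.start, rec.end, rec.dataset_id) == ("chr1", 100, 300, "ds")

    def test_narrowpeak_extra_columns_ignored(self, tmp_path):
        p = tmp_path / "a.narrowPeak"
        p.write_text("chr2\t10\t50\tpk\t0\t.\t4.5\t3.2\t1.1\t20\n")
        (rec,) = read_peaks(p, "ds")
        assert (rec.start, rec.end) == (10, 50)

    def test_headers_and_comments_skipped(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("track name=x\n# comment\nbrowser position chr1\nchr1\t0\t2\n")
        assert len(read_peaks(p, "ds")) == 1

    def test_inverted_interval_lenient_vs_strict(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chr1\t300\t100\n")
        assert read_peaks(p, "ds", strict=False) == []
        with pytest.raises(ValidationError):
            read_peaks(p, "ds", strict=True)

    def test_non_numeric_coordinates_fatal_even_when_lenient(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chr1\tzero\tten\n")
        with pytest.raises(FormatError):
            read_peaks(p, "ds", strict=False)

    def test_parsing_is_order_insensitive(self, tmp_path):
        lines = [f"chr1\t{i * 10}\t{i * 10 + 7}\n" for i in range(30)]
        shuffled = lines[:]
        random.Random(3).shuffle(shuffled)
        p1, p2 = tmp_path / "a.bed", tmp_path / "b.bed"
        p1.write_text("".join(lines))
        p2.write_text("".join(shuffled))
        c1 = sorted(compute_center(r).position for r in read_peaks(p1, "ds"))
        c2 = sorted(compute_center(r).position for r in read_peaks(p2, "ds"))
        assert c1 == c2


class TestComputeCenter:
    @pytest.mark.parametrize(
        "start,end,expected", [(100, 300, 200.0), (100, 301, 200.5), (0, 2, 1.0)]
    )
    def test_center_is_half_sum(self, start, end, expected):
        assert compute_center(PeakRecord("chr1", start, end, "d")).position == expected

    @given(
        a_start=st.integers(0, 10**6), a_len=st.integers(1, 1000),
        gap=st.integers(1, 1000), b_len=st.integers(1, 1000),
    )
    @settings(max_examples=100, derandomize=True)
    def test_center_is_monotone_for_disjoint_records(self, a_start, a_len, gap, b_len):
        a = PeakRecord("chr1", a_start, a_start + a_len, "d")
        b_start = a_start + a_len + gap
        b = PeakRecord("chr1", b_start, b_start + b_len, "d")
        assert compute_center(a).position < compute_center(b).position

    def test_invalid_record_rejected(self):
        with pytest.raises(ValidationError):
            PeakRecord("chr1", 5, 5, "d")
        with pytest.raises(ValidationError):
            PeakRecord("chr1", -1, 5, "d")


class TestWriteSites:
    def _calls(self):
        return [
            BindingSiteCall("chr1", 200.0, 180.0, 220.0, 10, 1.0, 20, True),
            BindingSiteCall("chr1", 500.0, 500.0, 500.0, 1, 0.1, 1, False),
            BindingSiteCall("chr2", 77.5, 70.0, 80.5, 9, 0.9, 18, False),
        ]

    def test_round_trip_preserves_summit_fraction_flag(self, tmp_path):
        path = tmp_path / "sites.bed"
        calls = self._calls()
        write_sites(calls, path, provenance=["unit-test run"])
        back = read_sites(path)
        assert len(back) == len(calls)
        for orig, rt in zip(calls, back):
            assert rt.summit == orig.summit
            assert abs(rt.cell_line_fraction - orig.cell_line_fraction) <= 0.0005
            assert rt.constitutive == orig.constitutive
            assert rt.n_peak_centers == orig.n_peak_centers

    def test_zero_width_region_written_as_unit_interval(self, tmp_path):
        path = tmp_path / "sites.bed"
        write_sites(self._calls(), path)
        line = [l for l in path.read_text().splitlines() if "\t500\t" in l][0]
        fields = line.split("\t")
        assert (fields[1], fields[2]) == ("500", "501")

    def test_score_is_thousandths_of_fraction(self, tmp_path):
        path = tmp_path / "sites.bed"
        write_sites(self._calls(), path)
        scores = [l.split("\t")[4] for l in path.read_text().splitlines() if not l.startswith("#")]
        assert scores == ["1000", "100", "900"]

    def test_empty_call_list_writes_empty_file(self, tmp_path):
        path = tmp_path / "sites.bed"
        write_sites([], path, provenance=["nothing"])
        assert read_sites(path) == []
        summary = (tmp_path / "sites.bed.summary.tsv").read_text()
        assert summary.startswith("chrom\t")

    def test_summary_totals_per_chromosome(self, tmp_path):
        path = tmp_path / "sites.bed"
        write_sites(self._calls(), path)
        rows = (tmp_path / "sites.bed.summary.tsv").read_text().splitlines()[1:]
        assert rows == ["chr1\t2\t1", "chr2\t1\t0"]
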