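"""Interval model, format round-trips, and interval-algebra oracles."""

import numpy as np
import pytest

from dreamtargets.genome import (
    CoverageTrack,
    GenomicInterval,
    PeakSet,
    load_coverage,
    load_gene_models,
    load_intervals,
    merge_intervals,
    overlap_fraction,
    rescale_to_midpoint,
    write_coverage,
    write_gene_models,
    write_intervals,
)

from conftest import coverage_mask, random_intervals


class TestIntervalModel:
    def test_invalid_coordinates_rejected(self):
        with pytest.raises(ValueError):
            GenomicInterval("chr1", 5, 5)
        with pytest.raises(ValueError):
            GenomicInterval("chr1", -1, 5)
        with pytest.raises(ValueError):
            GenomicInterval("", 0, 5)

    def test_half_open_length_and_midpoint(self):
        iv = GenomicInterval("chr1", 10, 21)
        assert iv.length == 11
        assert iv.midpoint == 15  # floor of the average

    def test_overlap_semantics(self):
        a = GenomicInterval("chr1", 0, 10)
        assert not a.overlaps(GenomicInterval("chr1", 10, 20))  # book-ended
        assert a.overlaps(GenomicInterval("chr1", 9, 20))
        assert not a.overlaps(GenomicInterval("chr2", 5, 6))


class TestBedIO:
    def test_minimal_line(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chr1\t10\t20\n")
        ps = load_intervals(p)
        assert len(ps) == 1
        assert (ps[0].chrom, ps[0].start, ps[0].end, ps[0].strand) == ("chr1", 10, 20, ".")

    def test_empty_file(self, tmp_path):
        p = tmp_path / "empty.bed"
        p.write_text("")
        assert len(load_intervals(p)) == 0

    def test_comment_and_track_lines_skipped(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("# header\ntrack name=x\nchr1\t1\t5\n")
        assert len(load_intervals(p)) == 1

    def test_malformed_line_names_line_number(self, tmp_path):
        p = tmp_path / "bad.bed"
        p.write_text("chr1\t1\t5\nchr1\t9\t3\n")
        with pytest.raises(ValueError, match=":2"):
            load_intervals(p)

    def test_roundtrip_byte_identical(self, tmp_path):
        rng = np.random.default_rng(7)
        peaks = PeakSet(
            [
                GenomicInterval(
                    f"chr{rng.integers(1, 4)}",
                    int(s := rng.integers(0, 10_000)),
                    int(s + rng.integers(1, 500)),
                    "+-."[rng.integers(0, 3)],
                    f"pk{i}",
                    float(rng.integers(0, 1000)),
                )
                for i in range(100)
            ]
        )
        f1, f2 = tmp_path / "a.bed", tmp_path / "b.bed"
        write_intervals(peaks, f1)
        write_intervals(load_intervals(f1), f2)
        assert f1.read_bytes() == f2.read_bytes()


class TestGff3:
    GFF = (
        "##gff-version 3\n"
        "chr1\tsrc\tgene\t4\t10\t.\t+\t.\tID=gA\n"
        "chr1\tsrc\tmRNA\t4\t10\t.\t+\t.\tID=gA.t1;Parent=gA\n"
        "chr1\tsrc\tgene\t4\t10\t.\t-\t.\tID=gB\n"
        "chr1\tsrc\tmRNA\t4\t10\t.\t-\t.\tID=gB.t1;Parent=gB\n"
    )

    def test_coordinate_conversion(self, tmp_path):
        p = tmp_path / "a.gff3"
        p.write_text(self.GFF)
        genes = {g.gene_id: g for g in load_gene_models(p)}
        assert (genes["gA"].span.start, genes["gA"].span.end) == (3, 10)

    def test_strand_aware_tss_tts(self, tmp_path):
        p = tmp_path / "a.gff3"
        p.write_text(self.GFF)
        genes = {g.gene_id: g for g in load_gene_models(p)}
        assert genes["gA"].tss_list == [3] and genes["gA"].tts_list == [9]
        # minus strand mRNA 4..10: TSS is the larger coordinate
        assert genes["gB"].tss_list == [9] and genes["gB"].tts_list == [3]

    def test_orphan_mrna_skipped_with_warning(self, tmp_path):
        p = tmp_path / "a.gff3"
        p.write_text(
            "##gff-version 3\nchr1\ts\tgene\t4\t10\t.\t+\t.\tID=gA\n"
            "chr1\ts\tmRNA\t20\t30\t.\t+\t.\tID=orphan;Parent=gX\n"
        )
        with pytest.warns(UserWarning, match="orphan"):
            genes = load_gene_models(p)
        assert [g.gene_id for g in genes] == ["gA"]

    def test_random_genes_roundtrip(self, tmp_path):
        from dreamtargets.genome import GeneModel

        rng = np.random.default_rng(8)
        genes = []
        for i in range(50):
            start = int(rng.integers(0, 100_000))
            end = start + int(rng.integers(600, 3000))
            strand = "+" if rng.random() < 0.5 else "-"
            tss, tts = [], []
            for _ in range(int(rng.integers(1, 4))):
                j5, j3 = int(rng.integers(0, 100)), int(rng.integers(0, 100))
                if strand == "+":
                    tss.append(start + j5)
                    tts.append(end - 1 - j3)
                else:
                    tss.append(end - 1 - j5)
                    tts.append(start + j3)
            genes.append(
                GeneModel(f"g{i}", GenomicInterval("chr1", start, end, strand), strand, tss, tts)
            )
        path = tmp_path / "rt.gff3"
        write_gene_models(genes, path)
        reloaded = {g.gene_id: g for g in load_gene_models(path)}
        for g in genes:
            r = reloaded[g.gene_id]
            assert (r.span.start, r.span.end, r.strand) == (g.span.start, g.span.end, g.strand)
            assert sorted(r.tss_list) == sorted(g.tss_list)
            assert sorted(r.tts_list) == sorted(g.tts_list)


class TestBedGraph:
    def test_expansion(self, tmp_path):
        p = tmp_path / "a.bg"
        p.write_text("chr1\t0\t3\t2.0\n")
        track = load_coverage(p, "chr1")
        assert track.values.tolist() == [2.0, 2.0, 2.0]

    def test_missing_chrom_gives_zero_track(self, tmp_path):
        p = tmp_path / "a.bg"
        p.write_text("chr2\t0\t3\t2.0\n")
        track = load_coverage(p, "chr1", length=5)
        assert track.values.tolist() == [0.0] * 5

    def test_total_signal_matches_record_sum(self, tmp_path):
        rng = np.random.default_rng(9)
        for trial in range(5):
            pos, rows, total = 0, [], 0.0
            for _ in range(30):
                pos += int(rng.integers(0, 20))
                ln = int(rng.integers(1, 50))
                val = float(rng.integers(0, 10))
                rows.append(f"chr1\t{pos}\t{pos + ln}\t{val}")
                total += ln * val
                pos += ln
            p = tmp_path / f"t{trial}.bg"
            p.write_text("\n".join(rows) + "\n")
            track = load_coverage(p, "chr1")
            assert track.values.sum() == pytest.approx(total)

    def test_overlap_and_negative_rejected(self, tmp_path):
        p = tmp_path / "a.bg"
        p.write_text("chr1\t0\t5\t1.0\nchr1\t3\t8\t1.0\n")
        with pytest.raises(ValueError, match="overlap"):
            load_coverage(p, "chr1")
        p.write_text("chr1\t0\t5\t-1.0\n")
        with pytest.raises(ValueError, match="negative"):
            load_coverage(p, "chr1")

    def test_write_read_roundtrip(self, tmp_path):
        rng = np.random.default_rng(10)
        values = rng.poisson(1.0, 500).astype(float)
        track = CoverageTrack("chr1", values)
        p = tmp_path / "rt.bg"
        write_coverage(track, p)
        back = load_coverage(p, "chr1", length=500)
        assert np.array_equal(back.values, values)


class TestMerge:
    def test_overlapping_pair(self):
        ps = PeakSet([GenomicInterval("c", 10, 20), GenomicInterval("c", 15, 30)])
        merged = merge_intervals(ps)
        assert [(iv.start, iv.end) for iv in merged] == [(10, 30)]

    def test_book_ended_intervals_merge(self):
        ps = PeakSet([GenomicInterval("c", 10, 20), GenomicInterval("c", 20, 30)])
        assert [(iv.start, iv.end) for iv in merge_intervals(ps)] == [(10, 30)]

    def test_disjoint_sorted_unchanged(self):
        ps = PeakSet([GenomicInterval("c", 50, 60), GenomicInterval("c", 10, 20)])
        assert [(iv.start, iv.end) for iv in merge_intervals(ps)] == [(10, 20), (50, 60)]

    def test_empty(self):
        assert len(merge_intervals(PeakSet())) == 0

    def test_conserves_covered_bases_and_idempotent(self):
        rng = np.random.default_rng(11)
        chroms = ("chr1", "chr2")
        peaks = random_intervals(rng, 300, chroms)
        merged = merge_intervals(peaks)
        assert coverage_mask(peaks, chroms, 11_000).keys() == coverage_mask(merged, chroms, 11_000).keys()
        for c in chroms:
            assert np.array_equal(
                coverage_mask(peaks, chroms, 11_000)[c], coverage_mask(merged, chroms, 11_000)[c]
            )
        # disjoint and idempotent
        again = merge_intervals(merged)
        assert [(iv.chrom, iv.start, iv.end) for iv in again] == [
            (iv.chrom, iv.start, iv.end) for iv in merged
        ]
        for a, b in zip(merged, merged.intervals[1:]):
            if a.chrom == b.chrom:
                assert a.end < b.start


class TestRescale:
    def test_fixed_point(self):
        out = rescale_to_midpoint(PeakSet([GenomicInterval("c", 100, 300)]), 100)
        assert (out[0].start, out[0].end) == (100, 300)

    def test_clipping_at_zero(self):
        out = rescale_to_midpoint(PeakSet([GenomicInterval("c", 0, 10)]), 100)
        assert (out[0].start, out[0].end) == (0, 105)

    def test_all_outputs_fixed_width(self):
        rng = np.random.default_rng(12)
        peaks = PeakSet(
            [
                GenomicInterval("c", int(s := rng.integers(200, 10_000)), int(s + rng.integers(1, 400)))
                for _ in range(200)
            ]
        )
        out = rescale_to_midpoint(peaks, 100)
        assert all(iv.length == 200 for iv in out)
        # midpoint is preserved for unclipped windows
        for before, after in zip(peaks, out):
            assert after.midpoint == before.midpoint


class TestOverlapFraction:
    def test_identical_sets(self):
        rng = np.random.default_rng(13)
        ps = random_intervals(rng, 50)
        assert overlap_fraction(ps, ps) == 1.0

    def test_disjoint_sets(self):
        a = PeakSet([GenomicInterval("c", 0, 10)])
        b = PeakSet([GenomicInterval("c", 100, 110)])
        assert overlap_fraction(a, b) == 0.0

    def test_empty_query_warns(self):
        with pytest.warns(UserWarning):
            assert overlap_fraction(PeakSet(), PeakSet([GenomicInterval("c", 0, 5)])) == 0.0

    def test_matches_all_pairs_oracle(self):
        rng = np.random.default_rng(14)
        query = random_intervals(rng, 500)
        ref = random_intervals(rng, 500)
        expected = np.mean(
            [any(q.overlaps(r) for r in ref) for q in query]
        )
        assert overlap_fraction(query, ref) == pytest.approx(expected)
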