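"""Gene/peak I/O, coordinate conventions, and strand-aware region assignment."""

import numpy as np
import pandas as pd
import pytest

from h33course.genome_io import (
    GeneCatalog,
    GeneModel,
    ParseError,
    Peak,
    Sample,
    SampleSheet,
    StepCoverage,
    ValidationError,
    assign_region,
    read_bedgraph,
    read_gene_models,
    read_matrix,
    read_sample_sheet,
    write_matrix,
    write_sample_sheet,
)


class TestGeneModels:
    def test_bed6_fields_map_directly(self, tmp_path):
        p = tmp_path / "genes.bed"
        p.write_text("chr1\t10000\t20000\tGeneA\t0\t+\n")
        cat = read_gene_models(p)
        g = cat["GeneA"]
        assert (g.chrom, g.start, g.end, g.strand) == ("chr1", 10000, 20000, "+")
        assert g.tss == 10000 and g.tts == 20000

    def test_empty_file_gives_empty_catalog(self, tmp_path):
        p = tmp_path / "empty.bed"
        p.write_text("")
        assert len(read_gene_models(p)) == 0

    def test_duplicate_gene_ids_rejected(self, tmp_path):
        p = tmp_path / "dup.bed"
        p.write_text("chr1\t0\t100\tA\t0\t+\nchr2\t0\t100\tA\t0\t-\n")
        with pytest.raises(ValidationError, match="duplicate"):
            read_gene_models(p)

    def test_malformed_line_names_line_number(self, tmp_path):
        p = tmp_path / "bad.bed"
        p.write_text("chr1\t0\t100\tA\t0\t+\nchr1\tnotanumber\t5\tB\t0\t+\n")
        with pytest.raises(ParseError, match="line 2"):
            read_gene_models(p)

    def test_start_ge_end_rejected(self, tmp_path):
        p = tmp_path / "bad.bed"
        p.write_text("chr1\t100\t100\tA\t0\t+\n")
        with pytest.raises(ValidationError):
            read_gene_models(p)

    def test_minus_strand_tss_is_end(self):
        g = GeneModel("X", "chr1", 30000, 40000, "-")
        assert g.tss == 40000 and g.tts == 30000
        assert g.promoter_window(3000) == (40000, 43000)

    def test_promoter_clamped_at_zero(self):
        g = GeneModel("X", "chr1", 1000, 5000, "+")
        assert g.promoter_window(3000) == (0, 1000)


class TestAssignRegion:
    @pytest.mark.parametrize(
        "peak,expected_cat,expected_gene",
        [
            (Peak("chr1", 7500, 8000), "promoter", "GeneA"),   # 3 kb upstream window
            (Peak("chr1", 12000, 12500), "genebody", "GeneA"),
            (Peak("chr1", 41000, 41200), "promoter", "GeneB"),  # minus strand, upstream of TSS=40000
            (Peak("chr1", 50_000, 50_500), "intergenic", None),
            (Peak("chr1", 6999, 7000), "intergenic", None),     # 1 bp left of the window
            (Peak("chr1", 9999, 10001), "promoter", "GeneA"),   # promoter beats genebody
        ],
    )
    def test_examples(self, toy_catalog, peak, expected_cat, expected_gene):
        a = assign_region(peak, toy_catalog, promoter_bp=3000)
        assert (a.category, a.gene_id) == (expected_cat, expected_gene)

    def test_unknown_chrom_downgrades_to_intergenic(self, toy_catalog, caplog):
        with caplog.at_level("WARNING"):
            a = assign_region(Peak("chrUn", 0, 100), toy_catalog)
        assert a.category == "intergenic"
        assert "unknown chromosome" in caplog.text

    def test_tie_breaks_by_tss_distance_then_id(self):
        cat = GeneCatalog(
            [
                GeneModel("B", "chr1", 1000, 2000, "+"),
                GeneModel("A", "chr1", 2500, 3500, "+"),
            ]
        )
        # peak inside both genebody(B)=no, spans gap: promoter(A)=[0? ...]
        # peak [1900, 2600) overlaps genebody B and genebody A; nearer TSS wins
        a = assign_region(Peak("chr1", 1900, 2600), cat, promoter_bp=100)
        assert a.category == "promoter"  # A's promoter [2400,2500) overlapped
        assert a.gene_id == "A"

    def test_agrees_with_per_base_oracle(self):
        # random toy genome; oracle labels every base, peak takes the highest-
        # precedence label among its overlapped bases
        rng = np.random.default_rng(42)
        genome_len = 100_000
        genes = []
        pos = 0
        i = 0
        while True:
            pos += int(rng.integers(2000, 6000))
            length = int(rng.integers(1000, 8000))
            if pos + length >= genome_len:
                break
            genes.append(GeneModel(f"g{i}", "chr1", pos, pos + length, rng.choice(["+", "-"])))
            pos += length
            i += 1
        cat = GeneCatalog(genes)
        promoter_bp = 3000
        base = np.zeros(genome_len + promoter_bp, dtype=np.int8)  # 0 intergenic, 1 genebody, 2 promoter
        for g in genes:
            base[g.start:g.end] = np.maximum(base[g.start:g.end], 1)
        for g in genes:
            p0, p1 = g.promoter_window(promoter_bp)
            base[p0:p1] = 2
        for _ in range(1000):
            s = int(rng.integers(0, genome_len - 500))
            e = s + int(rng.integers(50, 500))
            got = assign_region(Peak("chr1", s, e), cat, promoter_bp).category
            m = base[s:e].max()
            want = {0: "intergenic", 1: "genebody", 2: "promoter"}[int(m)]
            assert got == want, (s, e, got, want)


class TestBedgraph:
    def test_query_inside_and_outside(self, tmp_path):
        p = tmp_path / "c.bedGraph"
        p.write_text("chr1\t0\t100\t2.5\nchr1\t200\t300\t1.0\n")
        cov = read_bedgraph(p)
        assert cov.value_at("chr1", 50) == 2.5
        assert cov.value_at("chr1", 150) == 0.0
        assert cov.value_at("chr2", 50) == 0.0

    def test_overlapping_intervals_rejected(self, tmp_path):
        p = tmp_path / "c.bedGraph"
        p.write_text("chr1\t0\t100\t2.5\nchr1\t50\t150\t1.0\n")
        with pytest.raises(ValidationError, match="overlap"):
            read_bedgraph(p)

    def test_interval_sum_matches_per_base(self):
        rng = np.random.default_rng(0)
        pos, records = 0, []
        for _ in range(30):
            pos += int(rng.integers(0, 20))
            w = int(rng.integers(1, 50))
            records.append(("chr1", pos, pos + w, float(rng.uniform(0, 5))))
            pos += w
        cov = StepCoverage.from_records(records)
        for _ in range(50):
            s = int(rng.integers(0, pos))
            e = s + int(rng.integers(1, 200))
            brute = sum(cov.value_at("chr1", b) for b in range(s, e))
            assert cov.interval_sum("chr1", s, e) == pytest.approx(brute)


class TestMatrices:
    def test_round_trip_identity(self, tmp_path, sheet7):
        m = pd.DataFrame(
            [[0.1, 2.0000000001], [1e-9, 3.5]],
            index=["g1", "g2"],
            columns=["D0", "iPSC"],
        )
        path = tmp_path / "m.tsv"
        write_matrix(m, path, header="test")
        back = read_matrix(path, sheet7)
        pd.testing.assert_frame_equal(back, m.rename_axis("gene_id"))

    def test_unknown_sample_label_rejected(self, tmp_path, sheet7):
        path = tmp_path / "m.tsv"
        pd.DataFrame([[1.0]], index=["g"], columns=["NOPE"]).to_csv(path, sep="\t")
        with pytest.raises(ValidationError, match="NOPE"):
            read_matrix(path, sheet7)

    def test_non_numeric_cell_rejected(self, tmp_path):
        path = tmp_path / "m.tsv"
        path.write_text("gene_id\tD0\ng1\tabc\n")
        with pytest.raises(ValidationError):
            read_matrix(path)

    def test_column_order_preserved(self, tmp_path, sheet7, succ_labels):
        m = pd.DataFrame([range(7)], index=["g"], columns=succ_labels, dtype=float)
        path = tmp_path / "m.tsv"
        write_matrix(m, path)
        assert list(read_matrix(path).columns) == succ_labels


class TestSampleSheet:
    def test_default_route_orderings(self, sheet7):
        assert sheet7.successful_route("rna") == ["D0", "D3", "D6T-", "D9T-", "D12S+", "D16S+", "iPSC"]
        assert sheet7.unsuccessful_route("rna") == ["D6T+", "D9T+", "D12S-", "D16S-"]
        assert sheet7.day0_label("chip_ip") == "D0"

    def test_round_trip(self, tmp_path, sheet7):
        path = tmp_path / "sheet.tsv"
        write_sample_sheet(sheet7, path)
        back = read_sample_sheet(path)
        assert [(s.label, s.day, s.route, s.assay) for s in back.samples] == [
            (s.label, s.day, s.route, s.assay) for s in sheet7.samples
        ]

    def test_missing_day0_rejected(self):
        with pytest.raises(ValidationError, match="day-0"):
            SampleSheet([Sample("D3", 3, "shared", "rna")])

    def test_transdiff_design(self):
        sheet = SampleSheet.transdiff_3pt()
        assert sheet.successful_route("rna") == ["D0", "D4", "iHP"]
        assert sheet.unsuccessful_route("rna") == []
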