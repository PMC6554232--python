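"""Summary-statistics parsing, annotation handling, and gene scoring."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from netprop_gwas.errors import ConfigurationError, InputError
from netprop_gwas.gwas_io import (
    GeneAnnotation,
    SnpRecord,
    assign_gene_scores,
    normalize_chrom,
    read_gene_annotations,
    read_summary_stats,
)


def brute_force_scores(snps, genes, window_bp, p_floor=1e-300):
    """O(S*G) oracle: scan every SNP against every gene window."""
    out = {}
    for g in genes:
        best = None
        for s in snps:
            if s.chrom == g.chrom and g.start - window_bp <= s.pos <= g.end + window_bp:
                best = s.pvalue if best is None else min(best, s.pvalue)
        out[g.symbol] = 0.0 if best is None else -math.log10(max(p_floor, best))
    return out


def write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestReadSummaryStats:
    def test_plink_assoc_row(self, tmp_path):
        p = write(tmp_path, "a.assoc", "CHR SNP BP P\n21 rs123 25880550 9.56e-6\n")
        records, skipped = read_summary_stats(p)
        assert skipped == 0
        (r,) = records
        assert r == SnpRecord("rs123", "21", 25880550, 9.56e-6)

    def test_na_and_out_of_range_rows_skipped(self, tmp_path):
        p = write(
            tmp_path, "a.assoc",
            "CHR SNP BP P\n1 rs1 100 NA\n1 rs2 200 0.5\n1 rs3 300 1.5\n1 rs4 400 0\n",
        )
        records, skipped = read_summary_stats(p)
        assert [r.snp_id for r in records] == ["rs2"]
        assert skipped == 3

    def test_header_only_is_input_error(self, tmp_path):
        p = write(tmp_path, "a.assoc", "CHR SNP BP P\n")
        with pytest.raises(InputError):
            read_summary_stats(p)

    def test_missing_column_names_the_column(self, tmp_path):
        p = write(tmp_path, "a.assoc", "CHR SNP BP PVAL\n1 rs1 100 0.5\n")
        with pytest.raises(ConfigurationError, match="'P'"):
            read_summary_stats(p)

    def test_column_map_reads_snptest_style(self, tmp_path):
        p = write(
            tmp_path, "a.txt",
            "rsid chromosome position pvalue\nrs1 chr2 100 0.01\n",
        )
        records, _ = read_summary_stats(
            p, column_map={"snp": "rsid", "chrom": "chromosome",
                           "pos": "position", "p": "pvalue"},
        )
        assert records[0].chrom == "2"  # chr prefix stripped
        assert records[0].pvalue == 0.01

    def test_row_order_preserved(self, tmp_path):
        p = write(tmp_path, "a.assoc",
                  "CHR SNP BP P\n2 rsB 5 0.2\n1 rsA 9 0.1\n")
        records, _ = read_summary_stats(p)
        assert [r.snp_id for r in records] == ["rsB", "rsA"]


class TestChromNormalization:
    @pytest.mark.parametrize("raw,expected", [
        ("chr21", "21"), ("21", "21"), ("chrX", "X"), ("x", "X"),
        ("chrM", "MT"), ("MT", "MT"), ("ChrY", "Y"),
    ])
    def test_dialects_agree(self, raw, expected):
        assert normalize_chrom(raw) == expected


class TestReadGeneAnnotations:
    def test_bed_converts_to_one_based_inclusive(self, tmp_path):
        p = write(tmp_path, "g.bed", "chr21\t25880549\t25892000\tAPP\n")
        (g,) = read_gene_annotations(p)
        assert g == GeneAnnotation("APP", "21", 25880550, 25892000)

    def test_tabular_row_matches_bed(self, tmp_path):
        bed = write(tmp_path, "g.bed", "chr21\t25880549\t25892000\tAPP\n")
        tab = write(tmp_path, "g.tsv", "APP\t21\t25880550\t25892000\n")
        assert read_gene_annotations(bed) == read_gene_annotations(tab)

    def test_tabular_header_detected(self, tmp_path):
        p = write(tmp_path, "g.tsv",
                  "symbol\tchrom\tstart\tend\nAPP\t21\t100\t200\n")
        (g,) = read_gene_annotations(p)
        assert g.symbol == "APP" and g.start == 100

    def test_duplicate_symbol_merges_to_union_span(self, tmp_path):
        p = write(tmp_path, "g.tsv", "A\t1\t100\t200\nA\t1\t150\t400\n")
        (g,) = read_gene_annotations(p)
        assert (g.start, g.end) == (100, 400)

    def test_inverted_span_reports_line(self, tmp_path):
        p = write(tmp_path, "g.tsv", "A\t1\t100\t200\nB\t1\t500\t400\n")
        with pytest.raises(InputError, match=":2"):
            read_gene_annotations(p)


class TestAssignGeneScores:
    GENE = GeneAnnotation("APP", "21", 25880550, 25892000)

    def test_paper_style_single_snp_score(self):
        snp = SnpRecord("rs123", "21", 25880550, 9.56e-6)
        scores = assign_gene_scores([snp], [self.GENE], window_bp=10_000)
        assert scores["APP"] == pytest.approx(5.01954, abs=1e-4)

    def test_min_p_rule(self):
        snps = [SnpRecord("a", "21", 25880600, 0.5),
                SnpRecord("b", "21", 25880700, 0.01)]
        scores = assign_gene_scores(snps, [self.GENE])
        assert scores["APP"] == pytest.approx(2.0)

    def test_window_boundary_inclusive_at_exactly_window_bp(self):
        g = GeneAnnotation("G", "1", 1000, 2000)
        at_edge = SnpRecord("edge", "1", 2000 + 500, 1e-4)
        beyond = SnpRecord("out", "1", 2000 + 501, 1e-8)
        scores = assign_gene_scores([at_edge, beyond], [g], window_bp=500)
        assert scores["G"] == pytest.approx(4.0)
        assert scores.n_unmapped_snps == 1

    def test_snp_in_two_windows_counts_for_both(self):
        g1 = GeneAnnotation("G1", "1", 1000, 2000)
        g2 = GeneAnnotation("G2", "1", 2100, 3000)
        snp = SnpRecord("s", "1", 2050, 1e-3)
        scores = assign_gene_scores([snp], [g1, g2], window_bp=100)
        assert scores["G1"] == scores["G2"] == pytest.approx(3.0)

    def test_p_floor_keeps_scores_finite(self):
        snp = SnpRecord("s", "21", 25880600, 1e-320)
        scores = assign_gene_scores([snp], [self.GENE], p_floor=1e-300)
        assert scores["APP"] == pytest.approx(300.0)

    def test_empty_gene_list_rejected(self):
        with pytest.raises(InputError):
            assign_gene_scores([SnpRecord("s", "1", 5, 0.5)], [])

    def test_no_snps_gives_zero_vector(self):
        scores = assign_gene_scores([], [self.GENE])
        assert scores["APP"] == 0.0
        assert scores.n_scoreless_genes == 1

    @given(st.data())
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_matches_brute_force_oracle(self, data):
        rng_seed = data.draw(st.integers(0, 2**16))
        rng = np.random.default_rng(rng_seed)
        n_genes = data.draw(st.integers(1, 20))
        n_snps = data.draw(st.integers(0, 50))
        window = data.draw(st.sampled_from([0, 10, 500, 10_000]))
        genes = []
        for i in range(n_genes):
            start = int(rng.integers(1, 50_000))
            genes.append(GeneAnnotation(f"G{i}", str(rng.integers(1, 3)),
                                        start, start + int(rng.integers(0, 5000))))
        snps = [
            SnpRecord(f"s{j}", str(rng.integers(1, 3)),
                      int(rng.integers(1, 60_000)), float(rng.uniform(1e-8, 1)))
            for j in range(n_snps)
        ]
        got = assign_gene_scores(snps, genes, window_bp=window)
        expected = brute_force_scores(snps, genes, window)
        for sym, val in expected.items():
            assert got[sym] == pytest.approx(val, abs=1e-12)

    def test_score_invariant_to_input_order(self):
        rng = np.random.default_rng(0)
        genes = [GeneAnnotation(f"G{i}", "1", 1 + i * 3000, 2000 + i * 3000)
                 for i in range(10)]
        snps = [SnpRecord(f"s{j}", "1", int(rng.integers(1, 40_000)),
                          float(rng.uniform(0.001, 1))) for j in range(40)]
        fwd = assign_gene_scores(snps, genes)
        rev = assign_gene_scores(snps[::-1], genes[::-1])
        assert fwd.entries == rev.entries

    def test_monotone_in_pvalue_and_window(self):
        genes = [GeneAnnotation("G", "1", 1000, 2000)]
        snps = [SnpRecord("a", "1", 1500, 0.05), SnpRecord("b", "1", 2900, 0.2)]
        base = assign_gene_scores(snps, genes, window_bp=100)
        lower_p = assign_gene_scores(
            [SnpRecord("a", "1", 1500, 0.01), snps[1]], genes, window_bp=100)
        wider = assign_gene_scores(snps, genes, window_bp=1000)
        assert lower_p["G"] >= base["G"]
        assert wider["G"] >= base["G"]
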