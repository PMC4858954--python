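"""I/O round-trips, polarization and coordinate conventions."""

import numpy as np
import pandas as pd
import pytest

from haploscan.formats import (
    GeneInterval,
    HaplotypeMatrix,
    MarkerMap,
    read_gene_intervals,
    read_phased_vcf,
    read_results,
    set_ancestral,
    write_phased_vcf,
    write_regions_bed,
    write_results,
)

from conftest import make_map, random_hap


class TestPhasedVCF:
    def test_round_trip_exact(self, rng, tmp_path):
        hap = random_hap(rng, 40, 50)  # 20 samples x 50 SNPs
        mmap = make_map(50, chrom="3", spacing=977)
        path = tmp_path / "x.vcf"
        write_phased_vcf(hap, mmap, path)
        hap2, mmap2, samples = read_phased_vcf(path)
        np.testing.assert_array_equal(hap2.values, hap.values)
        np.testing.assert_array_equal(mmap2.pos, mmap.pos)
        assert list(mmap2.snp_id) == list(mmap.snp_id)
        assert samples == hap.sample_ids

    def test_dimensions_from_fixture(self, tmp_path):
        vcf = tmp_path / "t.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n##contig=<ID=1>\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ta\tb\n"
            "1\t100\ts1\tA\tG\t.\t.\t.\tGT\t0|1\t1|1\n"
            "1\t200\ts2\tC\tT\t.\t.\t.\tGT\t0|0\t0|1\n"
            "1\t300\ts3\tA\tC\t.\t.\t.\tGT\t1|0\t0|0\n"
        )
        hap, mmap, samples = read_phased_vcf(vcf)
        assert hap.values.shape == (4, 3)
        assert len(mmap) == 3
        # row order: sample a hapA, a hapB, b hapA, b hapB
        np.testing.assert_array_equal(hap.values[:, 0], [0, 1, 1, 1])

    @pytest.mark.parametrize("gt,msg", [("0/1", "unphased"), ("0|1", "multiallelic")])
    def test_rejects_bad_records(self, tmp_path, gt, msg):
        alt = "G" if msg == "unphased" else "G,T"
        vcf = tmp_path / "bad.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n##contig=<ID=1>\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ta\n"
            f"1\t100\ts1\tA\t{alt}\t.\t.\t.\tGT\t{gt}\n"
        )
        with pytest.raises(ValueError, match=msg):
            read_phased_vcf(vcf)


class TestSetAncestral:
    def _table(self, mmap, alleles):
        return pd.DataFrame({
            "snp_id": mmap.snp_id,
            "chrom:pos": [f"{c}:{p}" for c, p in zip(mmap.chrom, mmap.pos)],
            "ancestral_allele": alleles,
        })

    def test_alt_ancestral_flips_column(self, small_hap_map):
        hap, mmap = small_hap_map
        alleles = ["A"] * 50
        alleles[7] = "G"  # ALT is ancestral at SNP 7
        old_freq = hap.derived_freq()[7]
        hap2, mmap2 = set_ancestral(hap, mmap, self._table(mmap, alleles))
        np.testing.assert_array_equal(hap2.values[:, 7], 1 - hap.values[:, 7])
        assert mmap2.df.at[7, "ancestral"] == "alt"
        assert mmap2.df.at[7, "derived_freq"] == pytest.approx(1 - old_freq)

    def test_ref_everywhere_is_identity(self, small_hap_map):
        hap, mmap = small_hap_map
        hap2, mmap2 = set_ancestral(hap, mmap, self._table(mmap, ["A"] * 50))
        np.testing.assert_array_equal(hap2.values, hap.values)
        assert (mmap2.df["ancestral"] == "ref").all()

    def test_derived_freq_equals_column_mean(self, rng, small_hap_map):
        hap, mmap = small_hap_map
        alleles = rng.choice(["A", "G", "T"], size=50)  # T matches neither -> unknown
        with pytest.warns(UserWarning, match="unknown ancestral"):
            hap2, mmap2 = set_ancestral(hap, mmap, self._table(mmap, alleles))
        np.testing.assert_allclose(
            mmap2.df["derived_freq"].to_numpy(), hap2.values.mean(axis=0), atol=0)
        assert (mmap2.df.loc[alleles == "T", "ancestral"] == "unknown").all()


class TestGeneIntervals:
    def test_bed_coordinate_convention(self, tmp_path):
        bed = tmp_path / "g.bed"
        bed.write_text("chr5\t99\t200\tG1\n")
        (g,) = read_gene_intervals(bed)
        assert (g.start, g.end, g.name) == (100, 200, "G1")

    def test_gff3_is_one_based(self, tmp_path):
        gff = tmp_path / "g.gff3"
        gff.write_text("##gff-version 3\nchr5\tsrc\tgene\t100\t200\t.\t+\t.\tID=G1;Name=G1\n")
        (g,) = read_gene_intervals(gff)
        assert (g.start, g.end) == (100, 200)

    def test_dialects_agree_on_random_intervals(self, rng, tmp_path):
        starts = rng.integers(1, 10_000, size=20)
        ends = starts + rng.integers(0, 5_000, size=20)
        bed = tmp_path / "r.bed"
        gff = tmp_path / "r.gff3"
        bed.write_text("".join(f"c1\t{s - 1}\t{e}\tg{i}\n" for i, (s, e) in enumerate(zip(starts, ends))))
        gff.write_text("##gff-version 3\n" + "".join(
            f"c1\tsrc\tgene\t{s}\t{e}\t.\t+\t.\tID=g{i};Name=g{i}\n"
            for i, (s, e) in enumerate(zip(starts, ends))))
        from_bed = {(g.name, g.start, g.end) for g in read_gene_intervals(bed)}
        from_gff = {(g.name, g.start, g.end) for g in read_gene_intervals(gff)}
        assert from_bed == from_gff

    def test_inverted_interval_rejected(self):
        with pytest.raises(ValueError):
            GeneInterval("1", 200, 100, "bad")


class TestResultTables:
    def test_tsv_round_trip(self, tmp_path):
        df = pd.DataFrame({"snp_id": ["a", "b"], "pos": [1, 2], "ihs": [0.5, -1.25]})
        p = tmp_path / "t.tsv"
        write_results(df, p)
        pd.testing.assert_frame_equal(read_results(p), df)

    def test_empty_table_writes_header_only(self, tmp_path):
        p = tmp_path / "e.tsv"
        write_results(pd.DataFrame(columns=["snp_id", "pos"]), p)
        assert p.read_text() == "snp_id\tpos\n"

    def test_regions_bed_coordinates(self, tmp_path):
        regions = pd.DataFrame([{
            "chrom": "14", "window_id": 51, "first_sig_pos": 25_505_663,
            "last_sig_pos": 25_877_586, "n_sig_snps": 9,
        }])
        p = tmp_path / "r.bed"
        write_regions_bed(regions, p)
        fields = p.read_text().strip().split("\t")
        assert fields[:3] == ["14", "25505662", "25877586"]
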