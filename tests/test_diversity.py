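"""Four-fold site extraction, variant filtering and windowed diversity."""

import logging

import numpy as np
import pandas as pd
import pytest

from conftest import genotype_table, write_vcf
from linksel import diversity
from oracles import codon_walk_fourfold, hamming_pi


def _write_mini_genome(tmp_path, seq_by_chrom, cds_rows):
    """cds_rows: (chrom, start, end, strand, phase, parent)."""
    fasta = tmp_path / "mini.fa"
    with fasta.open("w") as fh:
        for chrom, seq in seq_by_chrom.items():
            fh.write(f">{chrom}\n{seq}\n")
    gff = tmp_path / "mini.gff3"
    with gff.open("w") as fh:
        fh.write("##gff-version 3\n")
        for chrom, start, end, strand, phase, parent in cds_rows:
            fh.write(
                f"{chrom}\ttest\tCDS\t{start}\t{end}\t.\t{strand}\t{phase}\t"
                f"ID={parent}.cds;Parent={parent}\n"
            )
    return fasta, gff


class TestFourfoldSites:
    def test_glycine_codon_third_position_reported(self, tmp_path):
        # ATG GGA TAA: GGA is glycine, GGN all glycine -> position 6
        fasta, gff = _write_mini_genome(
            tmp_path, {"chr1": "ATGGGATAA"}, [("chr1", 1, 9, "+", 0, "t1")]
        )
        sites = diversity.fourfold_sites(fasta, gff)
        assert sites.sites["pos"].tolist() == [6]

    def test_methionine_codon_not_reported(self, tmp_path):
        # ATG AAA TAA: neither ATG nor AAA (Lys <-> Asn) is four-fold
        fasta, gff = _write_mini_genome(
            tmp_path, {"chr1": "ATGAAATAA"}, [("chr1", 1, 9, "+", 0, "t1")]
        )
        assert len(diversity.fourfold_sites(fasta, gff).sites) == 0

    def test_minus_strand_gene(self, tmp_path):
        # reverse complement of ATG GGA TAA is TTATCCCAT; the GGA codon's
        # third base sits at genomic position 4 on the minus strand
        fasta, gff = _write_mini_genome(
            tmp_path, {"chr1": "TTATCCCAT"}, [("chr1", 1, 9, "-", 0, "t1")]
        )
        sites = diversity.fourfold_sites(fasta, gff)
        assert sites.sites["pos"].tolist() == [4]
        assert sites.sites["strand"].tolist() == ["-"]

    def test_overlapping_cds_must_agree(self, tmp_path):
        # transcript A reads GGA at 4-6 (pos 6 four-fold); transcript B is
        # shifted one frame so pos 6 is not a third position for it
        seq = "ATGGGACCCTAAAT"
        fasta, gff = _write_mini_genome(
            tmp_path,
            {"chr1": seq},
            [("chr1", 1, 12, "+", 0, "tA"), ("chr1", 2, 13, "+", 0, "tB")],
        )
        sites = diversity.fourfold_sites(fasta, gff)
        assert 6 not in sites.sites["pos"].tolist()

    def test_bad_length_transcript_skipped_with_warning(self, tmp_path, caplog):
        fasta, gff = _write_mini_genome(
            tmp_path,
            {"chr1": "ATGGGATAAC"},
            [("chr1", 1, 10, "+", 0, "bad"), ("chr1", 1, 9, "+", 0, "good")],
        )
        with caplog.at_level(logging.WARNING):
            sites = diversity.fourfold_sites(fasta, gff)
        assert "skipped" in caplog.text
        assert sites.n_skipped == 1
        assert sites.sites["pos"].tolist() == [6]

    def test_missing_chromosome_raises(self, tmp_path):
        fasta, gff = _write_mini_genome(
            tmp_path, {"chr1": "ATGGGATAA"}, [("chr2", 1, 9, "+", 0, "t1")]
        )
        with pytest.raises(ValueError, match="chr2"):
            diversity.fourfold_sites(fasta, gff)

    def test_toy_genome_matches_independent_codon_walk(self, toy_genome):
        sites = diversity.fourfold_sites(toy_genome.fasta, toy_genome.gff3)
        got = set(zip(sites.sites["chrom"], sites.sites["pos"]))
        oracle = codon_walk_fourfold(toy_genome.fasta, toy_genome.gff3)
        assert got == oracle
        planted = set(zip(toy_genome.fourfold["chrom"], toy_genome.fourfold["pos"]))
        assert got == planted


class TestFilterVariants:
    def test_qual_threshold_is_strict(self, tmp_path):
        vcf = write_vcf(
            tmp_path / "q.vcf",
            [
                ("chr1", 100, "A", "T", 19.9, None, ["0/1:30", "0/0:30"]),
                ("chr1", 200, "A", "T", 20.0, None, ["0/1:30", "0/0:30"]),
            ],
        )
        out = diversity.filter_variants(vcf, min_qual=20)
        assert out["pos"].tolist() == [200]

    def test_stringent_q30(self, tmp_path):
        vcf = write_vcf(
            tmp_path / "q30.vcf",
            [("chr1", 100, "A", "T", 25.0, None, ["0/1:30", "0/0:30"])],
        )
        assert len(diversity.filter_variants(vcf, min_qual=30)) == 0

    def test_invariant_site_exempt_from_variant_filters(self, tmp_path):
        vcf = write_vcf(
            tmp_path / "inv.vcf",
            [("chr1", 100, "A", ".", None, None, ["0/0:30", "0/0:30"])],
        )
        out = diversity.filter_variants(vcf)
        assert out["pos"].tolist() == [100]
        assert not out["is_variant"].iloc[0]

    def test_low_depth_sample_masked(self, tmp_path):
        # sample s1 mean depth 30; DP 14 < 0.5 * 30 masks its two alleles
        rows = [
            ("chr1", 100, "A", ".", None, None, ["0/0:38", "0/0:30"]),
            ("chr1", 200, "A", ".", None, None, ["0/0:38", "0/0:30"]),
            ("chr1", 300, "A", "T", 50.0, None, ["0/1:14", "0/0:30"]),
        ]
        out = diversity.filter_variants(write_vcf(tmp_path / "dp.vcf", rows))
        site = out[out["pos"] == 300].iloc[0]
        assert site["n_called"] == 2
        assert site["allele_counts"] == (2,)

    def test_strand_bias_filter(self, tmp_path):
        rows = [
            ("chr1", 100, "A", "T", 50.0, "FS=40.0", ["0/1:30", "0/0:30"]),
            ("chr1", 200, "A", "T", 50.0, "FS=39.9", ["0/1:30", "0/0:30"]),
        ]
        out = diversity.filter_variants(write_vcf(tmp_path / "fs.vcf", rows))
        assert out["pos"].tolist() == [200]

    def test_rank_sum_filter(self, tmp_path):
        rows = [
            ("chr1", 100, "A", "T", 50.0, "MQRankSum=-4.2", ["0/1:30", "0/0:30"]),
            ("chr1", 200, "A", "T", 50.0, "MQRankSum=3.9;BaseQRankSum=1.0",
             ["0/1:30", "0/0:30"]),
        ]
        out = diversity.filter_variants(write_vcf(tmp_path / "rs.vcf", rows))
        assert out["pos"].tolist() == [200]

    def test_empty_stream_yields_empty_table(self, tmp_path):
        out = diversity.filter_variants(write_vcf(tmp_path / "e.vcf", []))
        assert len(out) == 0

    def test_restriction_to_fourfold_sites(self, toy_genome):
        sites = diversity.fourfold_sites(toy_genome.fasta, toy_genome.gff3)
        out = diversity.filter_variants(toy_genome.vcf, sites)
        planted = set(zip(toy_genome.site_diffs["chrom"], toy_genome.site_diffs["pos"]))
        assert set(zip(out["chrom"], out["pos"])) == planted


class TestWindowPi:
    @staticmethod
    def _sites(positions, chrom="chr1"):
        df = pd.DataFrame({"chrom": chrom, "pos": positions, "strand": "+"})
        return diversity.FourfoldSiteSet(df, 1, 0)

    def test_two_two_split_single_site(self):
        table = genotype_table([("chr1", 10, (2, 2))])
        out = diversity.window_pi(table, self._sites([10]), 1000, min_sites=1)
        assert out["pi"].iloc[0] == pytest.approx(4 / 6)

    def test_monomorphic_window_zero(self):
        table = genotype_table([("chr1", p, (4,)) for p in (10, 20, 30)])
        out = diversity.window_pi(table, self._sites([10, 20, 30]), 1000, min_sites=1)
        assert out["pi"].iloc[0] == 0.0

    def test_min_sites_exclusion_boundary(self):
        positions = list(range(1, 500))  # 499 sites in the first window
        table = genotype_table([("chr1", p, (4,)) for p in positions])
        out = diversity.window_pi(table, self._sites(positions), 1000, min_sites=500)
        assert bool(out["excluded"].iloc[0])
        out2 = diversity.window_pi(table, self._sites(positions), 1000, min_sites=499)
        assert not out2["excluded"].iloc[0]

    def test_sex_chromosomes_excluded(self):
        table = genotype_table([("chrX", 10, (2, 2))])
        out = diversity.window_pi(
            table, self._sites([10], chrom="chrX"), 1000, min_sites=1,
            sex_chroms=("chrX",),
        )
        assert bool(out["excluded"].iloc[0])

    def test_single_called_haplotype_not_sequenced(self):
        table = genotype_table([("chr1", 10, (1,)), ("chr1", 20, (2, 2))])
        out = diversity.window_pi(table, self._sites([10, 20]), 1000, min_sites=1)
        assert out["n_sites"].iloc[0] == 1
        assert out["pi"].iloc[0] == pytest.approx(4 / 6)

    def test_sample_order_invariance(self):
        entries = [("chr1", 10, (3, 1)), ("chr1", 20, (1, 3)), ("chr1", 30, (2, 2))]
        a = diversity.window_pi(genotype_table(entries), self._sites([10, 20, 30]), 1000, min_sites=1)
        b = diversity.window_pi(
            genotype_table(list(reversed(entries))), self._sites([10, 20, 30]), 1000, min_sites=1
        )
        assert a["pi"].iloc[0] == pytest.approx(b["pi"].iloc[0])

    def test_site_duplication_leaves_per_site_pi_unchanged(self):
        entries = [("chr1", 10, (3, 1)), ("chr1", 20, (2, 2))]
        doubled = entries + [("chr1", 30, (3, 1)), ("chr1", 40, (2, 2))]
        a = diversity.window_pi(genotype_table(entries), self._sites([10, 20]), 1000, min_sites=1)
        b = diversity.window_pi(
            genotype_table(doubled), self._sites([10, 20, 30, 40]), 1000, min_sites=1
        )
        assert a["pi"].iloc[0] == pytest.approx(b["pi"].iloc[0])

    def test_added_difference_cannot_decrease_pi(self):
        base = [("chr1", 10, (3, 1)), ("chr1", 20, (4,))]
        more = [("chr1", 10, (3, 1)), ("chr1", 20, (3, 1))]
        a = diversity.window_pi(genotype_table(base), self._sites([10, 20]), 1000, min_sites=1)
        b = diversity.window_pi(genotype_table(more), self._sites([10, 20]), 1000, min_sites=1)
        assert b["pi"].iloc[0] >= a["pi"].iloc[0]

    def test_matches_brute_force_hamming_on_toy_genome(self, toy_genome):
        sites = diversity.fourfold_sites(toy_genome.fasta, toy_genome.gff3)
        table = diversity.filter_variants(toy_genome.vcf, sites)
        out = diversity.window_pi(
            table, sites, 2000, min_sites=1, n_haplotypes=toy_genome.n_haplotypes
        )
        # haplotype matrix from the planted variants; absent sites monomorphic
        for (chrom, start), grp in out.groupby(["chrom", "start"]):
            in_win = sites.sites[
                (sites.sites["chrom"] == chrom)
                & (sites.sites["pos"] > start)
                & (sites.sites["pos"] <= grp["end"].iloc[0])
            ]
            haps = np.zeros((toy_genome.n_haplotypes, len(in_win)), dtype=int)
            lookup = table.set_index(["chrom", "pos"])
            for j, pos in enumerate(in_win["pos"]):
                if (chrom, pos) in lookup.index:
                    counts = lookup.loc[(chrom, pos), "allele_counts"]
                    alleles = np.repeat(np.arange(len(counts)), counts)
                    haps[:, j] = alleles  # order irrelevant for pi
            assert grp["pi"].iloc[0] == pytest.approx(hamming_pi(haps))

    def test_zero_variant_fixture_all_windows_zero(self, tmp_path):
        from linksel import synthetic

        toy = synthetic.gen_toy_genome(3, tmp_path, variant_fraction=0.0)
        sites = diversity.fourfold_sites(toy.fasta, toy.gff3)
        table = diversity.filter_variants(toy.vcf, sites)
        out = diversity.window_pi(table, sites, 2000, min_sites=1, n_haplotypes=toy.n_haplotypes)
        assert (out["pi"].dropna() == 0).all()


class TestFunctionalDensity:
    def test_exon_fraction_of_windows(self, toy_genome):
        wins = pd.DataFrame(
            {"chrom": ["chr1", "chr1"], "start": [1000, 2000], "end": [2000, 3000]}
        )
        out = diversity.functional_density(toy_genome.gff3, wins)
        # gene1 CDS spans 1001..1300 -> 300 bp of the first window
        assert out["fd"].iloc[0] == pytest.approx(300 / 1000)
        assert out["fd"].iloc[1] == pytest.approx(600 / 1000)

    def test_density_bounded(self, toy_genome):
        wins = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [6000]})
        fd = diversity.functional_density(toy_genome.gff3, wins)["fd"]
        assert ((fd >= 0) & (fd <= 1)).all()
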