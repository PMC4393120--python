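import numpy as np
import pandas as pd
import pytest

from linksel import synthetic


@pytest.fixture(scope="session")
def toy_genome(tmp_path_factory):
    """Small FASTA/GFF3/VCF fixture with planted four-fold truth."""
    return synthetic.gen_toy_genome(11, tmp_path_factory.mktemp("toy"))


@pytest.fixture(scope="session")
def noiseless_species():
    """Noiseless joint BGS+HH species: windows, map truths and truth record."""
    cfg = synthetic.SimConfig(
        seed=42, n_windows=300, noise_cv=0.0, alpha_true=5e-10, U_true=1.0,
        sh_true=0.01,
    )
    windows, markers, maps, truth = synthetic.simulate_species(cfg)
    return cfg, windows, markers, maps, truth


def write_vcf(path, rows, samples=("s1", "s2"), contigs=("chr1",), info_fields=()):
    """Minimal hand-rolled VCF writer for filter tests.

    ``rows``: (chrom, pos, ref, alt, qual, info, genotype strings).
    """
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c in contigs:
            fh.write(f"##contig=<ID={c},length=100000>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="GT">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="DP">\n')
        fh.write('##INFO=<ID=FS,Number=1,Type=Float,Description="strand bias">\n')
        fh.write('##INFO=<ID=BaseQRankSum,Number=1,Type=Float,Description="z">\n')
        fh.write('##INFO=<ID=MQRankSum,Number=1,Type=Float,Description="z">\n')
        fh.write('##INFO=<ID=ReadPosRankSum,Number=1,Type=Float,Description="z">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples) + "\n")
        for chrom, pos, ref, alt, qual, info, gts in rows:
            fh.write(
                f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t{qual}\t.\t{info or '.'}\tGT:DP\t"
                + "\t".join(gts) + "\n"
            )
    return path


def genotype_table(entries):
    """Build a filtered-genotype table directly from (chrom, pos, counts)."""
    rows = [
        (chrom, pos, len(counts) > 1, sum(counts), tuple(counts))
        for chrom, pos, counts in entries
    ]
    return pd.DataFrame(
        rows, columns=["chrom", "pos", "is_variant", "n_called", "allele_counts"]
    )
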