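"""Four-fold degenerate site extraction, variant filtering and windowed pi.

Four-fold degenerate sites — third codon positions where every base encodes
the same amino acid — serve as the putatively neutral markers.  A genomic
position qualifies only if it is four-fold degenerate in *every* CDS
annotation overlapping it (conservative with respect to overlapping
transcripts).  Diversity is pi, the average number of pairwise differences
per site among sampled haplotypes, computed in non-overlapping windows from
genotype calls that survive the quality filters: site quality >= Q20 (or
the stricter Q30), per-sample depth at least half that sample's mean depth
at four-fold sites, and — for variable sites only — phred-scaled strand
bias below 40 and rank-sum Z statistics within +/-4.

Windows are 0-based half-open internally and 1-based in written reports.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path

import gffutils
import numpy as np
import pandas as pd
from cyvcf2 import VCF
from pyfaidx import Fasta

logger = logging.getLogger(__name__)

__all__ = [
    "FourfoldSiteSet",
    "fourfold_sites",
    "filter_variants",
    "window_pi",
    "functional_density",
    "FOURFOLD_PREFIXES",
]

_BASES = "ACGT"
_COMP = str.maketrans("ACGTacgt", "TGCAtgca")


def _fourfold_prefixes() -> frozenset[str]:
    from Bio.Data.CodonTable import standard_dna_table

    full = dict(standard_dna_table.forward_table)
    for stop in standard_dna_table.stop_codons:
        full[stop] = "*"
    return frozenset(
        p
        for p in {c[:2] for c in full}
        if len({full[p + b] for b in _BASES}) == 1
    )


#: The eight codon-prefix pairs whose third position is fully degenerate.
FOURFOLD_PREFIXES = _fourfold_prefixes()


@dataclass
class FourfoldSiteSet:
    """Four-fold degenerate positions per chromosome (1-based, sorted)."""

    sites: pd.DataFrame  # chrom, pos, strand
    n_transcripts: int
    n_skipped: int

    def positions(self, chrom: str) -> np.ndarray:
        return self.sites.loc[self.sites["chrom"] == chrom, "pos"].to_numpy()


def fourfold_sites(fasta_path: Path | str, gff_path: Path | str) -> FourfoldSiteSet:
    """Extract four-fold degenerate sites from a genome and its annotation.

    CDS features are grouped by parent transcript, ordered in translation
    direction, trimmed by the phase of the first segment, and walked codon
    by codon.  Transcripts whose phase-adjusted length is not a multiple of
    three (contradictory phase) are skipped with a warning.  A position is
    reported only if every CDS covering it marks it four-fold.
    """
    genome = Fasta(str(fasta_path), rebuild=False)
    db = gffutils.create_db(
        str(gff_path),
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    by_parent: dict[str, list] = defaultdict(list)
    orphan = 0
    for cds in db.features_of_type("CDS"):
        parents = cds.attributes.get("Parent") or cds.attributes.get("ID")
        if not parents:
            orphan += 1
            continue
        by_parent[parents[0]].append(cds)

    cover: dict[str, defaultdict[int, int]] = defaultdict(lambda: defaultdict(int))
    ffold: dict[str, defaultdict[int, int]] = defaultdict(lambda: defaultdict(int))
    strand_of: dict[tuple[str, int], str] = {}
    seq_cache: dict[str, str] = {}
    n_skipped = 0
    for parent, segs in by_parent.items():
        chrom = segs[0].seqid
        if chrom not in genome:
            raise ValueError(f"chromosome {chrom!r} in GFF3 absent from FASTA")
        strand = segs[0].strand
        segs = sorted(segs, key=lambda f: f.start)
        ordered = segs if strand == "+" else list(reversed(segs))
        coords: list[int] = []
        for seg in ordered:
            if strand == "+":
                coords.extend(range(seg.start, seg.end + 1))
            else:
                coords.extend(range(seg.end, seg.start - 1, -1))
        first_phase = ordered[0].frame
        phase = int(first_phase) if first_phase not in (None, ".", "") else 0
        if phase not in (0, 1, 2):
            logger.warning("transcript %s: invalid phase %r, skipped", parent, first_phase)
            n_skipped += 1
            continue
        coords = coords[phase:]
        if len(coords) % 3 != 0:
            logger.warning(
                "transcript %s: CDS length %d not divisible by 3 after phase "
                "adjustment, skipped",
                parent,
                len(coords),
            )
            n_skipped += 1
            continue
        if chrom not in seq_cache:
            seq_cache[chrom] = str(genome[chrom][:]).upper()
        seq = seq_cache[chrom]
        bases = [seq[p - 1] for p in coords]
        if strand == "-":
            bases = [b.translate(_COMP) for b in bases]
        for seg in segs:
            for p in range(seg.start, seg.end + 1):
                cover[chrom][p] += 1
        for ci in range(0, len(coords), 3):
            prefix = bases[ci] + bases[ci + 1]
            if prefix in FOURFOLD_PREFIXES:
                pos3 = coords[ci + 2]
                ffold[chrom][pos3] += 1
                strand_of[(chrom, pos3)] = strand
        # phase-trimmed leading bases still count as covered (they sit inside
        # the CDS) which keeps them from qualifying via another transcript
    rows = []
    for chrom, positions in ffold.items():
        for pos, n_ff in positions.items():
            if n_ff == cover[chrom][pos]:
                rows.append((chrom, pos, strand_of[(chrom, pos)]))
    sites = (
        pd.DataFrame(rows, columns=["chrom", "pos", "strand"])
        .sort_values(["chrom", "pos"])
        .reset_index(drop=True)
    )
    return FourfoldSiteSet(sites, len(by_parent), n_skipped)


def _genotype_alleles(record, sample_idx: int) -> list[int]:
    gt = record.genotypes[sample_idx]
    return [a for a in gt[:-1] if a is not None]


def filter_variants(
    vcf_path: Path | str,
    sites: FourfoldSiteSet | None = None,
    min_qual: float = 20.0,
    depth_fraction: float = 0.5,
    max_strand_bias: float = 40.0,
    max_ranksum_z: float = 4.0,
) -> pd.DataFrame:
    """Quality-filter VCF records down to a per-site genotype table.

    Variable sites need QUAL >= ``min_qual`` (phred probability of a
    segregating site; 20 by default, 30 for the stringent variant),
    strand bias (FS) below ``max_strand_bias`` and all of the base-quality,
    mapping-quality and read-position rank-sum Z scores within
    ``max_ranksum_z`` in absolute value; invariant records are exempt from
    all three.  Per sample, calls with depth below ``depth_fraction`` times
    that sample's mean depth across the retained four-fold records are
    masked.  Missing site annotations skip the corresponding filter with a
    logged count.  Returns one row per site with haplotype allele counts;
    an empty stream yields an empty table.
    """
    wanted: dict[str, set[int]] | None = None
    if sites is not None:
        wanted = {
            c: set(g["pos"].tolist())
            for c, g in sites.sites.groupby("chrom", sort=False)
        }
    vcf = VCF(str(vcf_path), gts012=False)
    n_samples = len(vcf.samples)
    kept = []
    missing_annotations = 0
    depth_sum = np.zeros(n_samples)
    depth_n = np.zeros(n_samples, dtype=int)
    for rec in vcf:
        if wanted is not None and rec.POS not in wanted.get(rec.CHROM, ()):
            continue
        alts = [a for a in rec.ALT if a not in (".", "<NON_REF>")]
        is_variant = len(alts) > 0
        if is_variant:
            if rec.QUAL is None or rec.QUAL < min_qual:
                continue
            fs = rec.INFO.get("FS")
            if fs is None:
                missing_annotations += 1
            elif fs >= max_strand_bias:
                continue
            bad_rank = False
            any_rank = False
            for key in ("BaseQRankSum", "MQRankSum", "ReadPosRankSum"):
                z = rec.INFO.get(key)
                if z is None:
                    continue
                any_rank = True
                if abs(z) > max_ranksum_z:
                    bad_rank = True
            if not any_rank:
                missing_annotations += 1
            if bad_rank:
                continue
        depths = rec.format("DP")
        depths = depths[:, 0].astype(float) if depths is not None else None
        if depths is not None:
            ok = depths >= 0
            depth_sum[ok] += depths[ok]
            depth_n[ok] += 1
        kept.append((rec.CHROM, rec.POS, is_variant, rec.genotypes, depths))
    if not kept:
        return pd.DataFrame(
            columns=["chrom", "pos", "is_variant", "n_called", "allele_counts"]
        )
    with np.errstate(invalid="ignore"):
        mean_depth = np.where(depth_n > 0, depth_sum / np.maximum(depth_n, 1), np.nan)
    if missing_annotations:
        logger.info(
            "%d variant records lacked bias/rank-sum annotations; those "
            "filters were skipped there",
            missing_annotations,
        )
    rows = []
    for chrom, pos, is_variant, genotypes, depths in kept:
        counts: defaultdict[int, int] = defaultdict(int)
        n_called = 0
        for s in range(n_samples):
            if (
                depths is not None
                and np.isfinite(mean_depth[s])
                and depths[s] < depth_fraction * mean_depth[s]
            ):
                continue  # sample masked at this site
            for a in genotypes[s][:-1]:
                if a is None or a < 0:
                    continue
                counts[a] += 1
                n_called += 1
        rows.append(
            (chrom, pos, is_variant, n_called, tuple(counts[k] for k in sorted(counts)))
        )
    return pd.DataFrame(
        rows, columns=["chrom", "pos", "is_variant", "n_called", "allele_counts"]
    )


def _site_pi(allele_counts: tuple[int, ...]) -> float:
    """Fraction of haplotype pairs differing at one site."""
    n = sum(allele_counts)
    if n < 2:
        return 0.0
    pairs = n * (n - 1) // 2
    same = sum(c * (c - 1) // 2 for c in allele_counts)
    return (pairs - same) / pairs


def window_pi(
    genotypes: pd.DataFrame,
    sites: FourfoldSiteSet,
    window_bp: int,
    min_sites: int = 500,
    sex_chroms: tuple[str, ...] = (),
    assume_missing_invariant: bool = True,
    n_haplotypes: int | None = None,
    chrom_sizes: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Per-window pairwise diversity at four-fold degenerate sites.

    Each site contributes its fraction of differing haplotype pairs,
    ``1 - sum_a C(n_a,2) / C(n,2)``; a window's pi is the summed
    contribution divided by the number of sequenced four-fold sites.  Sites
    with fewer than two called haplotypes contribute nothing and are not
    counted as sequenced.  With a variants-only VCF
    (``assume_missing_invariant``), four-fold sites absent from the
    genotype table count as sequenced and monomorphic provided
    ``n_haplotypes`` >= 2.  Windows under ``min_sites`` sequenced sites and
    windows on sex chromosomes are flagged excluded, not dropped.
    """
    geno = genotypes.set_index(["chrom", "pos"]) if len(genotypes) else genotypes
    rows = []
    for chrom, grp in sites.sites.groupby("chrom", sort=False):
        positions = grp["pos"].to_numpy()
        size = (
            chrom_sizes[chrom]
            if chrom_sizes and chrom in chrom_sizes
            else int(positions.max())
        )
        n_windows = int(np.ceil(size / window_bp))
        contrib = np.zeros(n_windows)
        n_seq = np.zeros(n_windows, dtype=int)
        for pos in positions:
            w = (pos - 1) // window_bp
            if len(genotypes) and (chrom, pos) in geno.index:
                row = geno.loc[(chrom, pos)]
                n_called = int(row["n_called"])
                if n_called < 2:
                    continue
                n_seq[w] += 1
                contrib[w] += _site_pi(tuple(row["allele_counts"]))
            elif assume_missing_invariant and (n_haplotypes or 0) >= 2:
                n_seq[w] += 1
        for w in range(n_windows):
            pi = contrib[w] / n_seq[w] if n_seq[w] > 0 else np.nan
            rows.append(
                (
                    chrom,
                    w * window_bp,
                    min((w + 1) * window_bp, size),
                    int(n_seq[w]),
                    pi,
                    n_seq[w] < min_sites or chrom in sex_chroms,
                )
            )
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "n_sites", "pi", "excluded"]
    )


def functional_density(
    gff_path: Path | str,
    windows: pd.DataFrame,
    feature_types: tuple[str, ...] = ("exon", "CDS"),
) -> pd.DataFrame:
    """Fraction of each window's bp covered by annotated exonic intervals.

    Uses ``exon`` features when present, else falls back to CDS.  Intervals
    are merged per chromosome before intersecting the (0-based half-open)
    windows.
    """
    db = gffutils.create_db(
        str(gff_path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    ftype = None
    for t in feature_types:
        if any(True for _ in db.features_of_type(t)):
            ftype = t
            break
    if ftype is None:
        raise ValueError(f"no {feature_types} features in {gff_path}")
    intervals: dict[str, list[tuple[int, int]]] = defaultdict(list)
    for feat in db.features_of_type(ftype):
        intervals[feat.seqid].append((feat.start - 1, feat.end))  # to half-open
    merged: dict[str, np.ndarray] = {}
    for chrom, ivs in intervals.items():
        ivs.sort()
        out = [list(ivs[0])]
        for s, e in ivs[1:]:
            if s <= out[-1][1]:
                out[-1][1] = max(out[-1][1], e)
            else:
                out.append([s, e])
        merged[chrom] = np.asarray(out)
    fd = np.zeros(len(windows))
    for i, (chrom, start, end) in enumerate(
        zip(windows["chrom"], windows["start"], windows["end"])
    ):
        if chrom not in merged:
            continue
        ivs = merged[chrom]
        overlap = np.clip(
            np.minimum(ivs[:, 1], end) - np.maximum(ivs[:, 0], start), 0, None
        )
        fd[i] = overlap.sum() / max(end - start, 1)
    out_df = windows.copy()
    out_df["fd"] = fd
    return out_df
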