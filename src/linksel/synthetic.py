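"""Synthetic inputs with known ground truth for every pipeline stage.

Nothing here simulates sequences forward in time: windowed diversity is
drawn around the same model expectation the fitting stage optimises
(``linksel.selection.predict_pi`` through the same ``compute_G`` code
path), which makes noiseless generation the exact inverse image of the
fitting stage and gives every downstream test a closed-form oracle.  The
generators emit the same plain-text formats the real-data paths consume
(FASTA, GFF3, VCF, TSV tables), with the planted truth carried alongside.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator
from scipy.optimize import brentq

from . import selection
from .selection import BgsParams, predict_pi, sweep_scaling

__all__ = [
    "SimConfig",
    "TruthRecord",
    "MareyTruth",
    "ToyGenome",
    "gen_marey_map",
    "gen_window_table",
    "gen_toy_genome",
    "gen_species_panel",
    "simulate_species",
    "simulate_impact_study",
    "PRESETS",
    "PANEL_COEFFICIENTS",
]


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulated species.

    The diversity-model parameters (theta, alpha, sh, U, P) mirror the
    fitting module's parameterisation; map parameters control the simulated
    Marey maps.  ``noise_cv`` is the coefficient of variation of the
    multiplicative mean-one Gamma window noise — the field reports no
    window-level dispersion to emulate, so this is a free study knob, not an
    estimate of any species' dispersion.
    """

    seed: int
    n_windows: int = 2000
    window_bp: int = 500_000
    theta_true: float = 0.01
    alpha_true: float = 0.0
    sh_true: float = 0.01
    U_true: float = 1.0
    P_true: float = 1.0
    noise_cv: float = 0.3
    model_set: int = 1
    fd_beta: tuple[float, float] = (2.0, 5.0)
    # map parameters
    n_markers: int = 150
    chrom_length_bp: int = 50_000_000
    map_length_cM: float = 100.0
    jitter_cM: float = 0.5
    incongruent_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.n_markers < 2:
            raise ValueError("n_markers must be >= 2")
        if self.map_length_cM <= 0:
            raise ValueError("map_length_cM must be positive")
        if not (0 < self.P_true <= 1):
            raise ValueError("P_true must lie in (0, 1]")
        if self.noise_cv < 0 or self.alpha_true < 0 or self.U_true < 0:
            raise ValueError("noise_cv, alpha_true and U_true must be non-negative")


#: CLI presets: canonical parameter regimes for quick simulation runs.
PRESETS: dict[str, dict] = {
    "neutral": dict(alpha_true=0.0, U_true=0.0),
    "bgs": dict(alpha_true=0.0, U_true=2.0, sh_true=3e-3, P_true=0.04),
    "hh": dict(alpha_true=5e-10, U_true=0.0),
    "joint": dict(alpha_true=3e-10, U_true=1.0, sh_true=0.01),
}


@dataclass
class TruthRecord:
    """Planted ground truth accompanying a generated artefact."""

    G: np.ndarray | None = None
    e_pi: np.ndarray | None = None
    rate_cMMb: np.ndarray | None = None
    impact: float | None = None
    coefficients: dict[str, float] | None = None
    displaced: np.ndarray | None = None
    extra: dict = field(default_factory=dict)


@dataclass
class MareyTruth:
    """The monotone truth function behind one simulated chromosome map."""

    chrom: str
    length_bp: int
    fn: Callable[[np.ndarray], np.ndarray]  # bp -> cM
    deriv: Callable[[np.ndarray], np.ndarray]  # bp -> cM per bp


def _truth_function(
    rng: np.random.Generator,
    length_bp: int,
    map_length_cM: float,
    anchors: tuple[Sequence[float], Sequence[float]] | None = None,
) -> tuple[Callable, Callable]:
    """Monotone cubic (PCHIP) through anchor points; random anchors by default."""
    if anchors is None:
        bp_anchor = np.linspace(0, length_bp, 6)
        incr = rng.gamma(2.0, 1.0, size=5)
        cm_anchor = np.concatenate([[0.0], np.cumsum(incr)])
        cm_anchor *= map_length_cM / cm_anchor[-1]
    else:
        bp_anchor = np.asarray(anchors[0], dtype=float)
        cm_anchor = np.asarray(anchors[1], dtype=float)
        if np.any(np.diff(bp_anchor) <= 0) or np.any(np.diff(cm_anchor) < 0):
            raise ValueError("truth anchors must be monotone")
    fn = PchipInterpolator(bp_anchor, cm_anchor)
    return fn, fn.derivative()


def gen_marey_map(
    config: SimConfig,
    *,
    chrom: str = "chr1",
    anchors: tuple[Sequence[float], Sequence[float]] | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, MareyTruth, TruthRecord]:
    """Simulate one chromosome's genetic-map markers.

    Physical positions are strictly increasing; genetic positions follow a
    smooth monotone truth function plus Gaussian jitter, and a stated
    fraction of markers is relocated to random genetic positions
    (incongruent).  The truth function is retained for derivative checks.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    fn, deriv = _truth_function(rng, config.chrom_length_bp, config.map_length_cM, anchors)
    bp = np.unique(rng.integers(1, config.chrom_length_bp, size=config.n_markers))
    while len(bp) < config.n_markers:  # collisions are rare at these densities
        extra = rng.integers(1, config.chrom_length_bp, size=config.n_markers - len(bp))
        bp = np.unique(np.concatenate([bp, extra]))
    bp = np.sort(bp)
    cM = np.asarray(fn(bp), dtype=float)
    if config.jitter_cM > 0:
        cM = cM + rng.normal(0.0, config.jitter_cM, size=len(bp))
    cM = np.clip(cM, 0.0, None)
    displaced = np.zeros(len(bp), dtype=bool)
    n_bad = round(config.incongruent_fraction * len(bp))
    if n_bad > 0:
        idx = rng.choice(len(bp), size=n_bad, replace=False)
        cM[idx] = rng.uniform(0.0, config.map_length_cM, size=n_bad)
        displaced[idx] = True
    markers = pd.DataFrame(
        {
            "marker": [f"{chrom}_m{i}" for i in range(len(bp))],
            "chrom": chrom,
            "bp": bp,
            "cM": cM,
            "displaced": displaced,
        }
    )
    truth = MareyTruth(chrom, config.chrom_length_bp, fn, deriv)
    return markers, truth, TruthRecord(displaced=displaced)


def gen_window_table(
    config: SimConfig,
    maps: MareyTruth | Sequence[MareyTruth],
    *,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, TruthRecord]:
    """Windowed diversity table drawn around the model expectation.

    Functional densities come from a Beta distribution (normalised inside
    the model code so genome-wide fractions sum to one); observed pi is the
    expectation times mean-one Gamma noise with CV ``noise_cv``.  The
    expectation runs through the same ``compute_G``/``predict_pi`` code the
    fitting module uses.
    """
    if isinstance(maps, MareyTruth):
        maps = [maps]
    if rng is None:
        rng = np.random.default_rng(config.seed)
    per_chrom = max(1, config.chrom_length_bp // config.window_bp)
    rows = []
    remaining = config.n_windows
    for m in maps:
        take = min(per_chrom, remaining)
        starts = np.arange(take, dtype=np.int64) * config.window_bp
        ends = starts + config.window_bp
        mids = (starts + ends) / 2.0
        rows.append(
            pd.DataFrame(
                {
                    "chrom": m.chrom,
                    "start": starts,
                    "end": ends,
                    "M_start": np.asarray(m.fn(starts)) / 100.0,
                    "M_end": np.asarray(m.fn(ends)) / 100.0,
                    "M_mid": np.asarray(m.fn(mids)) / 100.0,
                    "rate_cMMb": np.asarray(m.deriv(mids)) * 1e6,
                }
            )
        )
        remaining -= take
        if remaining <= 0:
            break
    if remaining > 0:
        raise ValueError(
            f"maps cover only {config.n_windows - remaining} of "
            f"{config.n_windows} requested windows"
        )
    windows = pd.concat(rows, ignore_index=True)
    windows["r_bp"] = windows["rate_cMMb"] * 1e-8
    windows["fd"] = rng.beta(*config.fd_beta, size=len(windows))
    fd_frac = windows["fd"].to_numpy() / windows["fd"].sum()

    params = BgsParams(U=config.U_true, sh=config.sh_true, P=config.P_true)
    G = selection.compute_G(windows, params)
    x = sweep_scaling(fd_frac, windows["r_bp"].to_numpy(), config.model_set)
    e_pi = predict_pi(config.theta_true, G, config.alpha_true, x)
    if config.noise_cv > 0:
        shape = 1.0 / config.noise_cv**2
        noise = rng.gamma(shape, 1.0 / shape, size=len(windows))
    else:
        noise = np.ones(len(windows))
    windows["pi"] = e_pi * noise
    windows["n_sites"] = config.window_bp // 100  # nominal sequenced 4-fold sites
    impact = float(np.clip(1.0 - e_pi.mean() / config.theta_true, 0.0, 1.0))
    truth = TruthRecord(
        G=G, e_pi=e_pi, rate_cMMb=windows["rate_cMMb"].to_numpy(), impact=impact
    )
    return windows, truth


def simulate_species(
    config: SimConfig,
) -> tuple[pd.DataFrame, list[pd.DataFrame], list[MareyTruth], TruthRecord]:
    """Maps plus window table for a whole genome (one map per chromosome)."""
    rng = np.random.default_rng(config.seed)
    per_chrom = max(1, config.chrom_length_bp // config.window_bp)
    n_chrom = math.ceil(config.n_windows / per_chrom)
    marker_tables, truths = [], []
    for c in range(n_chrom):
        markers, mtruth, _ = gen_marey_map(config, chrom=f"chr{c + 1}", rng=rng)
        marker_tables.append(markers)
        truths.append(mtruth)
    windows, truth = gen_window_table(config, truths, rng=rng)
    return windows, marker_tables, truths, truth


# ---------------------------------------------------------------------------
# toy genome fixture (FASTA + GFF3 + VCF with known four-fold sites)
# ---------------------------------------------------------------------------

_BASES = "ACGT"
_COMP = str.maketrans("ACGT", "TGCA")

_CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L", "CTT": "L", "CTC": "L",
    "CTA": "L", "CTG": "L", "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V", "TCT": "S", "TCC": "S",
    "TCA": "S", "TCG": "S", "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T", "GCT": "A", "GCC": "A",
    "GCA": "A", "GCG": "A", "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q", "AAT": "N", "AAC": "N",
    "AAA": "K", "AAG": "K", "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W", "CGT": "R", "CGC": "R",
    "CGA": "R", "CGG": "R", "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}
_NONSTOP = [c for c, aa in _CODON_TABLE.items() if aa != "*"]
_FOURFOLD_PREFIXES = {
    p for p in {c[:2] for c in _CODON_TABLE}
    if len({_CODON_TABLE[p + b] for b in _BASES}) == 1
}


@dataclass
class ToyGenome:
    """Paths and planted truth of a small FASTA/GFF3/VCF fixture."""

    fasta: Path
    gff3: Path
    vcf: Path
    fourfold: pd.DataFrame  # chrom, pos (1-based), strand
    site_diffs: pd.DataFrame  # chrom, pos, diff_pairs, n_called
    n_haplotypes: int


def _make_gene(rng: np.random.Generator, n_codons: int) -> str:
    body = "".join(rng.choice(_NONSTOP, size=n_codons - 2))
    return "ATG" + body + "TAA"


def gen_toy_genome(
    seed: int,
    out_dir: Path | str,
    *,
    n_samples: int = 4,
    variant_fraction: float = 0.4,
) -> ToyGenome:
    """Write a small multi-gene genome fixture with known four-fold sites.

    Two chromosomes, genes on both strands (one spliced gene exercising a
    non-zero phase), and a VCF of ``n_samples`` diploid samples with
    variants planted at a fraction of the four-fold sites plus decoy
    variants at non-four-fold positions.  The per-site pairwise-difference
    totals of the planted genotypes are returned as truth.
    """
    rng = np.random.default_rng(seed)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    chrom_len = 6000
    seqs = {
        c: list(rng.choice(list(_BASES), size=chrom_len)) for c in ("chr1", "chr2")
    }
    # gene layout: (chrom, strand, [(start, end), ...]) with 1-based inclusive
    # coordinates; spliced genes list exons in genomic order.
    genes = [
        ("chr1", "+", [(1001, 1300)]),
        ("chr1", "-", [(2001, 2600)]),
        ("chr1", "+", [(3001, 3100), (3201, 3400)]),
        ("chr2", "-", [(501, 800)]),
        ("chr2", "+", [(1501, 2100)]),
    ]
    fourfold_rows: list[tuple[str, int, str]] = []
    gff_lines = ["##gff-version 3"]
    for gi, (chrom, strand, exons) in enumerate(genes, 1):
        total = sum(e - s + 1 for s, e in exons)
        assert total % 3 == 0
        cds = _make_gene(rng, total // 3)
        # genomic coordinate of each spliced-CDS base, in translation order
        coords: list[int] = []
        if strand == "+":
            for s, e in exons:
                coords.extend(range(s, e + 1))
        else:
            for s, e in reversed(exons):
                coords.extend(range(e, s - 1, -1))
        for base, pos in zip(cds, coords):
            seqs[chrom][pos - 1] = base if strand == "+" else base.translate(_COMP)
        for ci in range(0, total, 3):
            codon = cds[ci : ci + 3]
            if codon[:2] in _FOURFOLD_PREFIXES:
                fourfold_rows.append((chrom, coords[ci + 2], strand))
        gid = f"gene{gi}"
        gff_lines.append(
            f"{chrom}\ttoy\tgene\t{exons[0][0]}\t{exons[-1][1]}\t.\t{strand}\t.\tID={gid}"
        )
        gff_lines.append(
            f"{chrom}\ttoy\tmRNA\t{exons[0][0]}\t{exons[-1][1]}\t.\t{strand}\t.\t"
            f"ID={gid}.t1;Parent={gid}"
        )
        # phase: bases to skip at the start of each segment in translation order
        ordered = exons if strand == "+" else list(reversed(exons))
        done = 0
        phases = {}
        for s, e in ordered:
            phases[(s, e)] = (3 - done % 3) % 3
            done += e - s + 1
        for s, e in exons:
            gff_lines.append(
                f"{chrom}\ttoy\tCDS\t{s}\t{e}\t.\t{strand}\t{phases[(s, e)]}\t"
                f"ID={gid}.cds;Parent={gid}.t1"
            )

    fasta = out_dir / "toy.fa"
    with fasta.open("w") as fh:
        for chrom, seq in seqs.items():
            fh.write(f">{chrom}\n")
            s = "".join(seq)
            for i in range(0, len(s), 60):
                fh.write(s[i : i + 60] + "\n")
    gff3 = out_dir / "toy.gff3"
    gff3.write_text("\n".join(gff_lines) + "\n")

    fourfold = (
        pd.DataFrame(fourfold_rows, columns=["chrom", "pos", "strand"])
        .drop_duplicates(subset=["chrom", "pos"])
        .sort_values(["chrom", "pos"])
        .reset_index(drop=True)
    )

    # plant variants: diploid genotypes at a fraction of four-fold sites
    n_hap = 2 * n_samples
    vcf_rows = []
    diff_rows = []
    ff_index = set(zip(fourfold["chrom"], fourfold["pos"]))
    n_var = round(variant_fraction * len(fourfold))
    chosen = rng.choice(len(fourfold), size=n_var, replace=False) if n_var else []
    for i in sorted(chosen):
        chrom, pos = fourfold.loc[i, "chrom"], int(fourfold.loc[i, "pos"])
        ref = seqs[chrom][pos - 1]
        alt = rng.choice([b for b in _BASES if b != ref])
        ac = int(rng.integers(1, n_hap))  # segregating by construction
        hap = np.zeros(n_hap, dtype=int)
        hap[rng.choice(n_hap, size=ac, replace=False)] = 1
        gts = [f"{hap[2 * s]}/{hap[2 * s + 1]}:30" for s in range(n_samples)]
        vcf_rows.append((chrom, pos, ref, alt, 50.0, gts))
        diff_rows.append((chrom, pos, ac * (n_hap - ac), n_hap))
    # decoy variants outside the four-fold set (must not affect pi)
    for chrom in seqs:
        pos = 1 + int(rng.integers(0, chrom_len))
        while (chrom, pos) in ff_index:
            pos = 1 + int(rng.integers(0, chrom_len))
        ref = seqs[chrom][pos - 1]
        alt = rng.choice([b for b in _BASES if b != ref])
        gts = ["0/1:30"] + ["0/0:30"] * (n_samples - 1)
        vcf_rows.append((chrom, pos, ref, alt, 50.0, gts))
    vcf_rows.sort(key=lambda r: (r[0], r[1]))

    vcf = out_dir / "toy.vcf"
    with vcf.open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in seqs:
            fh.write(f"##contig=<ID={chrom},length={chrom_len}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Depth">\n')
        samples = "\t".join(f"s{i + 1}" for i in range(n_samples))
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{samples}\n")
        for chrom, pos, ref, alt, qual, gts in vcf_rows:
            fh.write(
                f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t{qual}\t.\t.\tGT:DP\t"
                + "\t".join(gts)
                + "\n"
            )

    site_diffs = pd.DataFrame(
        diff_rows, columns=["chrom", "pos", "diff_pairs", "n_called"]
    )
    return ToyGenome(fasta, gff3, vcf, fourfold, site_diffs, n_hap)


# ---------------------------------------------------------------------------
# multi-species panels for the comparative module
# ---------------------------------------------------------------------------

#: Default planted coefficients of the species-level linear model
#: impact ~ log10(range) + log10(size) + kingdom + log10(size):kingdom.
#: Slopes sit in the empirically plausible range; intercept and predictor
#: ranges keep the noiseless linear predictor inside (0, 1) so clamping
#: never distorts recovery.
PANEL_COEFFICIENTS: dict[str, float] = {
    "intercept": -0.30,
    "log10_range": 0.11,
    "log10_size": -0.09,
    "kingdom": 0.12,
    "size_kingdom": -0.05,
}

CONFOUNDER_COLUMNS = (
    "marker_density",
    "frac_useable_markers",
    "nongap_fraction",
    "anchored_fraction",
    "mean_recomb_rate",
    "log10_c_value",
)


def gen_species_panel(
    n_species: int,
    coefficients: Mapping[str, float] | None = None,
    noise_sd: float = 0.05,
    seed: int = 0,
    confounder_coefficients: Mapping[str, float] | None = None,
) -> tuple[pd.DataFrame, TruthRecord]:
    """Species table whose impact follows the planted linear model.

    log10(size) ~ U(-2, 1.5) (metres), log10(range) ~ U(5.5, 8) (km^2),
    kingdom ~ Bernoulli(1/2); impact is the linear predictor plus Gaussian
    noise, clamped to [0, 1].  Confounder columns (map quality, assembly
    quality, mean recombination rate, genome size) are drawn independently
    and contribute the optional planted partial effects.
    """
    if n_species < 10:
        raise ValueError("need n_species >= 10 for the linear models to be well posed")
    coefs = dict(PANEL_COEFFICIENTS)
    if coefficients:
        coefs.update(coefficients)
    rng = np.random.default_rng(seed)
    log10_size = rng.uniform(-2.0, 1.5, n_species)
    log10_range = rng.uniform(5.5, 8.0, n_species)
    kingdom = rng.integers(0, 2, n_species)
    df = pd.DataFrame(
        {
            "species": [f"sp{i + 1}" for i in range(n_species)],
            "kingdom": kingdom,
            "log10_size": log10_size,
            "log10_range": log10_range,
            "marker_density": rng.uniform(0.1, 5.0, n_species),
            "frac_useable_markers": rng.beta(8, 2, n_species),
            "nongap_fraction": rng.beta(20, 2, n_species),
            "anchored_fraction": rng.beta(10, 2, n_species),
            "mean_recomb_rate": rng.uniform(0.5, 3.0, n_species),
            "log10_c_value": rng.normal(0.0, 0.5, n_species),
        }
    )
    linpred = (
        coefs["intercept"]
        + coefs["log10_range"] * log10_range
        + coefs["log10_size"] * log10_size
        + coefs["kingdom"] * kingdom
        + coefs["size_kingdom"] * log10_size * kingdom
    )
    if confounder_coefficients:
        for col, gamma in confounder_coefficients.items():
            linpred = linpred + gamma * df[col].to_numpy()
    noise = rng.normal(0.0, noise_sd, n_species) if noise_sd > 0 else 0.0
    df["impact"] = np.clip(linpred + noise, 0.0, 1.0)
    truth = TruthRecord(
        coefficients=coefs,
        extra={"confounder_coefficients": dict(confounder_coefficients or {})},
    )
    return df, truth


# ---------------------------------------------------------------------------
# impact-recovery study (planted impacts spanning 0 .. 0.7)
# ---------------------------------------------------------------------------


def _solve_impact_U(config: SimConfig, target: float, maps) -> float:
    """U achieving the target impact through background selection alone."""
    base = replace(config, U_true=1.0, alpha_true=0.0, noise_cv=0.0)
    windows, _ = gen_window_table(base, maps, rng=np.random.default_rng(config.seed))
    g1 = selection.compute_G(
        windows, BgsParams(U=1.0, sh=config.sh_true, P=config.P_true)
    )

    def f(U: float) -> float:
        return 1.0 - float(np.mean(np.exp(-U * g1))) - target

    if target <= 0:
        return 0.0
    hi = 1.0
    while f(hi) < 0 and hi < 1e9:
        hi *= 2.0
    return float(brentq(f, 0.0, hi, xtol=1e-12))


def _solve_impact_alpha(config: SimConfig, target: float, maps) -> float:
    """alpha achieving the target impact on top of the configured BGS."""
    base = replace(config, alpha_true=0.0, noise_cv=0.0)
    rng = np.random.default_rng(config.seed)
    windows, _ = gen_window_table(base, maps, rng=rng)
    G = selection.compute_G(
        windows, BgsParams(U=config.U_true, sh=config.sh_true, P=config.P_true)
    )
    fd_frac = windows["fd"].to_numpy() / windows["fd"].sum()
    x = sweep_scaling(fd_frac, windows["r_bp"].to_numpy(), config.model_set)
    eG = np.exp(G)

    def f(alpha: float) -> float:
        return 1.0 - float(np.mean(1.0 / (eG + alpha * x))) - target

    if f(0.0) >= 0:
        return 0.0
    hi = 1.0 / max(float(np.median(x[np.isfinite(x) & (x > 0)])), 1e-300)
    while f(hi) < 0 and hi < 1e30:
        hi *= 4.0
    return float(brentq(f, 0.0, hi, xtol=1e-30, rtol=1e-12))


@dataclass
class StudySpecies:
    """One simulated species of the recovery study, with fitting inputs."""

    windows: pd.DataFrame
    config: SimConfig
    true_impact: float
    selfing_class: str
    u_values: list[float]


def simulate_impact_study(
    n_species: int = 100,
    n_windows: int = 2000,
    noise_cv: float = 0.3,
    seed: int = 0,
    max_impact: float = 0.7,
) -> list[StudySpecies]:
    """Species panel with planted impacts spanning 0 .. ``max_impact``.

    Mixture of regimes: 40% background selection only (selfing-plant-like,
    P = 0.04, high-impact BGS is only reachable with reduced effective
    recombination), 30% joint BGS + sweeps, 30% sweep-dominated outcrossers.
    Target impacts are drawn uniformly and realised exactly (before noise)
    by root-finding on U or alpha against the model expectation; sh_true is
    drawn from the fitting grid and the species' mutation-rate bookkeeping
    puts U_true on the fitted U grid, so the truth lies on the model family
    the pipeline searches.
    """
    rng = np.random.default_rng(seed)
    sh_choices = selection.sh_grid()[5:11]  # ~3e-4 .. 3e-2, away from the edges
    out: list[StudySpecies] = []
    exonic, genome = 3.0e7, 1.0e9
    for i in range(n_species):
        kind = ("bgs", "joint", "hh")[
            0 if i % 10 < 4 else (1 if i % 10 < 7 else 2)
        ]
        target = float(rng.uniform(0.0, max_impact if kind != "bgs" else 0.5))
        sp_seed = int(rng.integers(0, 2**31 - 1))
        sh_true = float(rng.choice(sh_choices))
        if kind == "bgs":
            cfg = SimConfig(
                seed=sp_seed, n_windows=n_windows, noise_cv=noise_cv,
                sh_true=sh_true, P_true=0.04, alpha_true=0.0,
                map_length_cM=60.0,
            )
            selfing_class = "selfing"
        else:
            cfg = SimConfig(
                seed=sp_seed, n_windows=n_windows, noise_cv=noise_cv,
                sh_true=sh_true, P_true=1.0,
                U_true=0.2 if kind == "hh" else 1.0,
            )
            selfing_class = "outcrossing"
        _, _, maps, _ = _species_maps(cfg)
        if kind == "bgs":
            U = _solve_impact_U(cfg, target, maps)
            cfg = replace(cfg, U_true=U)
        elif kind == "joint":
            bg_target = target * float(rng.uniform(0.3, 0.7))
            U = _solve_impact_U(cfg, bg_target, maps)
            cfg = replace(cfg, U_true=U)
            alpha = _solve_impact_alpha(cfg, target, maps)
            cfg = replace(cfg, alpha_true=alpha)
        else:
            alpha = _solve_impact_alpha(cfg, target, maps)
            cfg = replace(cfg, alpha_true=alpha)
        windows, truth = gen_window_table(
            cfg, maps, rng=np.random.default_rng(cfg.seed)
        )
        # U grid of the fitting stage: anchor Umin at the species' own U so
        # the generative truth is inside the searched family
        if cfg.U_true > 0:
            mu = cfg.U_true / (2.0 * exonic)
            u_values = list(selection.u_grid(mu, exonic, genome).values())
        else:
            u_values = list(selection.u_grid(1e-8, exonic, genome).values())
        out.append(
            StudySpecies(
                windows=windows,
                config=cfg,
                true_impact=truth.impact,
                selfing_class=selfing_class,
                u_values=u_values,
            )
        )
    return out


def _species_maps(config: SimConfig) -> tuple:
    rng = np.random.default_rng(config.seed)
    per_chrom = max(1, config.chrom_length_bp // config.window_bp)
    n_chrom = math.ceil(config.n_windows / per_chrom)
    marker_tables, truths = [], []
    for c in range(n_chrom):
        markers, mtruth, _ = gen_marey_map(config, chrom=f"chr{c + 1}", rng=rng)
        marker_tables.append(markers)
        truths.append(mtruth)
    return None, marker_tables, truths, None
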