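"""Independent brute-force oracles used by the unit and acceptance tests.

Everything here is deliberately naive — exhaustive enumeration, O(n^2) pair
counting, direct formula evaluation — and shares no code with the package
paths it checks.
"""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np


def brute_force_lnds_length(values) -> int:
    """Length of the longest weakly increasing subsequence, by enumeration."""
    values = list(values)
    best = 0
    for r in range(len(values), 0, -1):
        for idx in combinations(range(len(values)), r):
            seq = [values[i] for i in idx]
            if all(a <= b for a, b in zip(seq, seq[1:])):
                return r
    return best


def hamming_pi(haplotypes: np.ndarray) -> float:
    """Mean pairwise Hamming distance per site over all haplotype pairs.

    ``haplotypes``: (n_hap, n_sites) integer allele matrix, -1 = missing.
    Sites are weighted by their own number of comparable pairs, matching a
    per-site n_called basis.
    """
    n_hap, n_sites = haplotypes.shape
    total = 0.0
    n_used = 0
    for s in range(n_sites):
        col = haplotypes[:, s]
        called = col[col >= 0]
        if len(called) < 2:
            continue
        pairs = diffs = 0
        for a, b in combinations(called, 2):
            pairs += 1
            diffs += a != b
        total += diffs / pairs
        n_used += 1
    return total / n_used if n_used else float("nan")


def kendall_tau_b(x, y) -> float:
    """Tie-corrected Kendall tau by O(n^2) pair counting."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    conc = disc = tx = ty = 0
    n = len(x)
    for i, j in combinations(range(n), 2):
        dx, dy = x[i] - x[j], y[i] - y[j]
        if dx == 0 and dy == 0:
            tx += 1
            ty += 1
        elif dx == 0:
            tx += 1
        elif dy == 0:
            ty += 1
        elif dx * dy > 0:
            conc += 1
        else:
            disc += 1
    n0 = n * (n - 1) / 2
    denom = math.sqrt((n0 - tx) * (n0 - ty))
    return (conc - disc) / denom


def partial_tau(x, y, z) -> float:
    t_xy, t_xz, t_yz = kendall_tau_b(x, y), kendall_tau_b(x, z), kendall_tau_b(y, z)
    return (t_xy - t_xz * t_yz) / math.sqrt((1 - t_xz**2) * (1 - t_yz**2))


def wilcoxon_enumerated_p(x, y) -> float:
    """Two-sided rank-sum p by enumerating all group assignments."""
    x, y = list(x), list(y)
    pooled = x + y
    n1 = len(x)
    obs = sum(sorted(pooled).index(v) + 1 for v in x)  # rank sum (no ties)
    ranks = {v: r + 1 for r, v in enumerate(sorted(pooled))}
    obs = sum(ranks[v] for v in x)
    mean_w = n1 * (len(pooled) + 1) / 2
    count = total = 0
    for idx in combinations(range(len(pooled)), n1):
        w = sum(ranks[pooled[i]] for i in idx)
        total += 1
        if abs(w - mean_w) >= abs(obs - mean_w) - 1e-12:
            count += 1
    return count / total


def fisher_enumerated_p(table) -> float:
    """Two-sided Fisher p: sum of hypergeometric probs <= the observed one."""
    (a, b), (c, d) = table
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2

    def prob(k: int) -> float:
        return (
            math.comb(r1, k) * math.comb(r2, c1 - k) / math.comb(n, c1)
        )

    p_obs = prob(a)
    return sum(
        prob(k)
        for k in range(max(0, c1 - r2), min(r1, c1) + 1)
        if prob(k) <= p_obs * (1 + 1e-9)
    )


def akaike_weights_direct(aics) -> list[float]:
    """Relative likelihoods e^((AICmin - AIC)/2), normalised."""
    amin = min(aics)
    rel = [math.exp((amin - a) / 2) for a in aics]
    s = sum(rel)
    return [r / s for r in rel]


def codon_walk_fourfold(fasta_path, gff_path) -> set[tuple[str, int]]:
    """Four-fold degenerate sites by an independent walk over the GFF3.

    Parses both files directly (no shared code with the package), builds
    each transcript's spliced CDS, translates codon by codon against a
    literal genetic-code dict, and applies the every-overlapping-CDS rule.
    """
    seqs: dict[str, str] = {}
    name = None
    chunks: list[str] = []
    for line in open(fasta_path):
        line = line.strip()
        if line.startswith(">"):
            if name is not None:
                seqs[name] = "".join(chunks)
            name = line[1:].split()[0]
            chunks = []
        else:
            chunks.append(line)
    if name is not None:
        seqs[name] = "".join(chunks)

    aa = {
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
    comp = str.maketrans("ACGT", "TGCA")

    transcripts: dict[str, list[tuple[str, int, int, str, int]]] = {}
    for line in open(gff_path):
        if line.startswith("#") or not line.strip():
            continue
        f = line.rstrip("\n").split("\t")
        if f[2] != "CDS":
            continue
        attrs = dict(kv.split("=", 1) for kv in f[8].split(";") if "=" in kv)
        parent = attrs.get("Parent", attrs.get("ID"))
        phase = int(f[7]) if f[7] not in (".", "") else 0
        transcripts.setdefault(parent, []).append(
            (f[0], int(f[3]), int(f[4]), f[6], phase)
        )

    cover: dict[tuple[str, int], int] = {}
    ffold: dict[tuple[str, int], int] = {}
    for segs in transcripts.values():
        segs = sorted(segs, key=lambda s: s[1])
        chrom, strand = segs[0][0], segs[0][3]
        ordered = segs if strand == "+" else list(reversed(segs))
        coords = []
        for _, s, e, _, _ in ordered:
            coords.extend(range(s, e + 1) if strand == "+" else range(e, s - 1, -1))
        coords = coords[ordered[0][4]:]
        if len(coords) % 3:
            continue
        bases = [seqs[chrom][p - 1].upper() for p in coords]
        if strand == "-":
            bases = [b.translate(comp) for b in bases]
        for _, s, e, _, _ in segs:
            for p in range(s, e + 1):
                cover[(chrom, p)] = cover.get((chrom, p), 0) + 1
        for ci in range(0, len(coords), 3):
            codon = bases[ci] + bases[ci + 1] + bases[ci + 2]
            if len({aa[codon[:2] + b] for b in "ACGT"}) == 1:
                key = (chrom, coords[ci + 2])
                ffold[key] = ffold.get(key, 0) + 1
    return {k for k, v in ffold.items() if v == cover[k]}
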