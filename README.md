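# linksel

How much neutral genetic diversity does natural selection at linked sites
remove — and does it remove more in species with larger census populations?

`linksel` is a Python package for population geneticists studying linked
selection comparatively.  It takes, per species, a reference genome
(FASTA), a protein-coding annotation (GFF3), population variant calls
(VCF) and a pedigree-based genetic map, and produces an estimate of the
*impact of selection*: the fraction of putatively neutral diversity
removed by background selection (BGS) and hitchhiking (HH).  A
cross-species layer relates those impacts to census-size proxies (body
size and geographic range), and a synthetic-data layer generates every
input with planted ground truth so the whole pipeline is testable without
any downloads.

## The model

Neutral diversity is measured as π at four-fold degenerate sites in
non-overlapping windows (100 kb / 500 kb / 1 Mb).  Expected diversity in
window *i* combines both selective forces on the coalescence rate:

    E[π_i] = θ_neutral / ( exp(G_i) + α · fd_i / rbp_i )

where `rbp_i` is the local recombination rate per bp (from the derivative
of a Marey-map fit), `fd_i` the window's share of the genome's functional
(exonic) sites, α a compound sweep-intensity parameter, and `G_i` the
background-selection coefficient summing over windows *k* of the same
chromosome:

    G_i = Σ_k U fd_k sh² / [ (sh + P|M_i − M_k|) (sh + P|M_i − M_{k+1}|) ]

with genetic positions M in Morgans, U the diploid deleterious mutation
rate, sh the compound selection × dominance parameter and P the index of
panmixis (1 outcrossing … 0.04 high selfing).  U, sh and P are profiled
over a grid; θ and α are fitted by bounded least squares.  Four model
classes — BGS+HH, BGS-only, HH-only, neutral — compete by AIC, Akaike
weights quantify support, and the impact of selection is
`max(0, 1 − observed mean π / θ_neutral)`.

See `docs/methods.md` for the full account: filters, map curation, the
fitting grid, AIC accounting (including a structural bound on the neutral
model's weight), and what the synthetic generators do and do not emulate.

## Worked example

Simulate a species with both selective forces, fit the model family, and
recover the planted impact:

```python
from linksel import selection, synthetic

cfg = synthetic.SimConfig(
    seed=9, n_windows=400, noise_cv=0.2,
    U_true=1.0, sh_true=0.00464, alpha_true=2e-6,
)
windows, markers, maps, truth = synthetic.simulate_species(cfg)
summary = selection.fit_selection(
    windows, u_values=[0.6, 1.0, 3.0], selfing_class="outcrossing",
)
print(f"true impact      {truth.impact:.4f}")
print(f"estimated impact {summary.impact:.4f}")
print(f"best model       {summary.best_model}")
print(f"weights          { {m: round(w, 3) for m, w in summary.weights.items()} }")
```

Output:

```
true impact      0.2313
estimated impact 0.2307
best model       BGS+HH
weights          {'neutral': 0.0, 'HH-only': 0.5, 'BGS-only': 0.0, 'BGS+HH': 0.5}
```

The planted 23% reduction in neutral diversity is recovered to three
decimals.  The sweep-containing models carry all the Akaike weight —
neutral and BGS-only are decisively rejected — while HH-only and BGS+HH
split it evenly: the background-selection component of this simulation is
mild enough that the extra G term buys no AIC advantage, exactly the kind
of honest ambiguity the weights are meant to expose.

The same flow works from the shell on real files:

```bash
linksel pi-windows --fasta ref.fa --gff genes.gff3 --vcf calls.vcf \
    --window-size 500000 --qual 20 --out windows_pi.tsv
linksel recmap --map map.tsv --windows windows_pi.tsv --method auto --out rates.tsv
linksel fit-selection --windows joined.tsv --exonic-bases 3e7 \
    --genome-size 1e9 --selfing-class outcrossing
linksel compare --records species.tsv --model main
```

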