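# Methods

## The problem

Across species, neutral genetic diversity varies far less than census
population size does.  One candidate explanation is selection at linked
sites: both purifying selection against deleterious mutations (background
selection, BGS) and the fixation of beneficial alleles (hitchhiking, HH)
remove neutral variation in proportion to how tightly it is linked to the
targets of selection, and both act more efficiently in larger populations.
`linksel` implements a pipeline that quantifies this effect species by
species — from windowed neutral diversity and recombination-rate
estimation through explicit model fitting to cross-species regression —
together with a synthetic-data layer that plants known truth behind every
stage.

## Windowed neutral diversity (`linksel.diversity`)

Putatively neutral markers are four-fold degenerate sites: third codon
positions where all four bases encode the same amino acid.  A position
qualifies only if *every* CDS annotation overlapping it marks it four-fold
(overlapping transcripts in different frames disqualify a site); this
all-transcripts rule is a conservative choice the underlying data do not
dictate.  Transcripts whose phase-adjusted CDS length is not a multiple of
three are skipped with a warning.

Genotype filters, in order: variable sites need a phred-scaled site
quality of at least 20 (a stricter Q30 mode is a switch); per sample,
calls with depth below half that sample's mean depth across four-fold
sites are masked; variable sites with phred-scaled strand bias (FS) of 40
or more, or any base-quality / mapping-quality / read-position rank-sum Z
outside ±4, are dropped.  Invariant sites are exempt from the
variant-level filters.  The rank-sum rule is implemented as *retaining*
|Z| ≤ 4; the configurable threshold lives on the `filter_variants`
signature.  Missing annotations skip the corresponding filter with a
logged count rather than failing.

Diversity is π, the average number of pairwise differences per site: each
site contributes `1 − Σ_a C(n_a,2) / C(n,2)` on its own called-haplotype
count n (no projection to a common sample size), and a window's π is the
summed contribution divided by its number of sequenced four-fold sites.
Windows with fewer than 500 sequenced four-fold sites, and all windows on
user-listed sex chromosomes, are flagged excluded.  Windows are 0-based
half-open internally, 1-based in written reports.

## Recombination rates from Marey maps (`linksel.marey`)

The genetic map is reconciled with the assembly by flagging as congruent a
maximum-length *weakly* increasing subsequence of genetic positions taken
in physical order (ties allowed — dense maps share cM values), computed by
a patience-sorting algorithm and verified against brute-force enumeration
in the tests.  Markers with several candidate placements keep the
candidate inside that subsequence; among several qualifying candidates the
one closest (in cM) to the linear interpolation of flanking congruent
single-placement markers wins — the tie-break is this package's own
choice.  Runs of at least five incongruent markers (chromosomes with ≥ 25
markers) or ⌈0.2 n⌉ (smaller chromosomes) mask the spanned interval;
chromosomes with fewer than five markers are masked entirely.

A polynomial (degree searched in 1 … max(3, min(20, ⌊n/3⌋))) or a linear
B-spline (degrees of freedom searched in 1 … min(100, max(2, ⌊n/2⌋))) is
fitted through the retained markers; the complexity with the best —
lowest — Gaussian least-squares AIC wins, with a literal
AIC-maximisation switch available but off (the phrase "maximises the AIC"
in the source literature is read as an optimisation slip).  Spline df
below two basis functions is infeasible for a degree-1 basis and is
skipped with a log entry.  Near-exact fits (RSS below ~(10⁻⁹ × map
span)² per marker) are floored so the simplest exact fit wins rather than
float noise.  The automatic method choice uses the polynomial for sparse
maps (mean intermarker spacing > 2 cM) and the spline otherwise.

Window rates are the fitted derivative at the window's physical midpoint
(cM/Mb), halved when a single-sex map represents a both-sex species,
clamped below at zero, then winsorized at the 99th percentile of the
clamped rates across all windows of the species (genome-wide, not per
chromosome; clamping precedes the percentile — both choices undocumented
in the source and fixed here).  `r_bp = rate_cMMb × 1e−8` converts to
crossovers per bp per generation.  Midpoints outside the fitted marker
span are evaluated anyway and flagged extrapolated.

## The diversity model (`linksel.selection`)

Expected diversity in window *i*:

    E[π_i] = θ_neutral / ( exp(G_i) + α · x_i )

with `x_i = fd_i / rbp_i` (model set 1, sweeps scaled by local functional
density) or `1 / rbp_i` (model set 2, homogeneous sweeps).  α is the
compound 2N·Vbp·J₂,₂; its factors are never separately identified.  The
background-selection coefficient sums over windows k on the same
chromosome:

    G_i = Σ_k U fd_k sh² / [ (sh + P|M_i − M_k|) (sh + P|M_i − M_{k+1}|) ]

with M in Morgans, `fd` normalised so the genome-wide fractions sum to
one, U the diploid genome-wide deleterious rate, sh the compound
selection × dominance parameter and P the index of panmixis.  Two
deliberate readings: the fraction bar lost in some renderings of the
formula is restored (a product form would grow with distance, which is
not a background-selection model), and the deleterious input is
attributed to the *contributing* window k rather than the focal window —
the focal-density form would make the sum independent of where the
deleterious sites lie.  A `literal_fd_focal` switch preserves the printed
focal form.  The printed sh² exponent is kept as-is; since sh is a free
grid dimension the exponent is absorbed into the grid and a second
exponent mode would add surface without changing any testable behaviour.
Cross-chromosome terms are omitted: a window 0.5 M away contributes
~4 × 10⁻⁴ of a fully linked one at sh = 0.01.

Nuisance grid: U ∈ {Umin = 2μ·exonic, Uconst = 1, Umax = 2μ·min(5·exonic,
genome size)}; sh, 13 points log-spaced on [10⁻⁵, 0.1] (count
configurable; the source count is unstated); P ∈ {1, 0.68, 0.04} for
outcrossers, partial selfers (~50%) and high selfers (~98%), all three
when the selfing class is unknown.  Per grid point, bounded least squares
fits θ > 0 and α ≥ 0 — α is profiled on a coarse log grid whose best
points seed multi-start `least_squares` (α₀ ∈ {0, grid optimum, ±3×}),
with θ available in closed form given α.  The BGS-only model (α = 0) and
the neutral model (θ̂ = mean π) have closed forms; HH-only sets G = 0.
Windows with zero recombination rate receive the smallest positive rate
(logged); a constant sweep regressor leaves the HH term unidentifiable
and flags the fit degenerate.

Model comparison uses AIC = n ln(RSS/n) + 2(k+1), k = 2 (BGS+HH), 1
(BGS-only), 2 (HH-only), 1 (neutral), +1 for the residual variance; grid
parameters are not counted, the constant term is dropped identically
across models.  The best AIC per class feeds relative likelihoods
exp((AICmin − AIC_j)/2), normalised to Akaike weights summing to one.
Support classes: < 0.05 low, [0.05, 0.9) medium, ≥ 0.9 high, with the HH
class pooling the HH-only and BGS+HH weights.  The impact of selection is
`max(0, 1 − observed mean π / θ_neutral)`, θ from the overall best-AIC
model.

A structural consequence of this AIC accounting, worth knowing when
reading the weights: the HH-only model nests the neutral model (α = 0),
so its best RSS never exceeds the neutral RSS and its AIC never exceeds
the neutral AIC by more than 2; likewise the sh grid reaches values where
G ≈ 0, letting the BGS-only class tie the neutral fit at equal parameter
count.  The neutral model's *normalised* weight is therefore bounded near
1/(2 + 2e⁻¹) ≈ 0.37 even on perfectly neutral data — strong support for
neutrality in the ≥ 0.9 sense is unreachable under this model set, and
the model-selection validation below reports the measured fractions
rather than pretending otherwise.

## Comparative layer (`linksel.comparative`)

Partial Kendall τ uses the first-order formula
`(τ_xy − τ_xz τ_yz)/√((1−τ_xz²)(1−τ_yz²))` with tie-corrected τ-b
throughout (tie handling is this package's choice).  The permutation test
for group differences uses the difference in means (medians available),
enumerates exhaustively when feasible and otherwise includes the identity
permutation in both numerator and denominator so p > 0.  Wilcoxon
rank-sum tests are exact (enumeration) for small tie-free samples and
asymptotic above a configurable size; Fisher's exact test is two-sided by
the minimum-likelihood rule (sum of tables no more probable than the
observed one).

The main species-level model is OLS of impact on log10(range),
log10(size), kingdom (0 animal, 1 plant) and the size × kingdom
interaction.  Confounder handling fits the nuisance-only model (two map
-quality measures, two assembly-quality measures, mean recombination
rate, genome size), the combined model, their nested F comparison, and
the census-size proxies against the nuisance-model residuals — a
conservative lower bound that attenuates any proxy effect collinear with
a confounder.  Census-size quadrants use strict inequalities against the
medians: high-Nc = larger-than-median range and smaller-than-median size;
low-Nc the opposite; species at a median stay unclassified.

## What the generators emulate (`linksel.synthetic`)

No coalescent or forward simulation: windowed π is drawn around the same
model expectation the fitting stage optimises, through the same
`compute_G`/`predict_pi` code, so noiseless generation is the exact
inverse image of fitting (the tests require RSS ≤ 10⁻¹² and machine-level
parameter recovery there).  What this validates is the estimation
machinery — identifiability, optimisation, model selection — not the
adequacy of the expectation as a description of real coalescent noise.
Real data differ in ways the generator deliberately ignores: correlated
window noise along chromosomes, non-Gamma dispersion, mutation-rate and
ascertainment heterogeneity, and real G landscapes that are not drawn
from the fitted family.

Choices, with defaults:

- **Window noise**: multiplicative mean-one Gamma with shape 1/CV², CV
  0.3 by default.  No window-level dispersion is reported for real
  species, so the CV is a free study knob; multiplicative noise keeps π
  non-negative.
- **Functional density**: Beta(2, 5) per window (right-skewed, mean 2/7),
  normalised downstream.
- **Marey truth functions**: monotone cubics (PCHIP) through six anchor
  points with Gamma-distributed genetic increments; markers get Gaussian
  cM jitter (0.5 cM default) and a stated fraction is relocated uniformly
  to emulate incongruent placements.  Non-monotone anchor requests are
  rejected.
- **Genome layout**: 500-kb windows, 50-Mb chromosomes (100 windows
  each), 100 cM per chromosome, as many chromosomes as the requested
  window count needs.
- **Toy genome fixture**: two ~6-kb chromosomes, five genes covering both
  strands and a spliced CDS with non-zero phase, VCF with planted diploid
  genotypes at a fraction of the four-fold sites plus decoy variants
  outside them; the planted per-site pairwise-difference totals ship as
  truth.
- **Species panels**: log10(size) ~ U(−2, 1.5) m, log10(range) ~ U(5.5,
  8) km², kingdom Bernoulli(1/2); impact is the planted linear predictor
  plus Gaussian noise, clamped to [0, 1].  Default slopes (range 0.11,
  size −0.09, kingdom 0.12, interaction −0.05, intercept −0.30) keep the
  noiseless predictor strictly inside (0, 1) so clamping never biases
  recovery tests.  Confounder columns are drawn independently with
  optional planted partial effects.

## The recovery study

`simulate_impact_study` plants impacts spanning 0–0.7 across 100 species
of 2000 windows each: 40% BGS-only selfing-plant-like species (P = 0.04 —
strong background selection needs reduced effective recombination), 30%
joint, 30% sweep-dominated outcrossers.  Target impacts are drawn
uniformly and realised exactly (before noise) by Brent root-finding on U
or α against the model expectation; sh_true is drawn from the fitting
grid, and each species' mutation-rate bookkeeping places its true U on
the fitted U grid, so the truth lies on the searched family and the study
isolates estimation error.  Under these conditions the pipeline recovers
impact with mean absolute error around 0.01 and rank correlation above
0.99 (the test bounds are 0.05 and 0.9); detection replicates at 500
windows identify a BGS-containing model on background-selection data
essentially always.  Problem sizes (100 × 2000; 50-replicate detection
runs at 500 windows) are the package's chosen validation scale.

## Numerical details and limitations

- RSS values are floored at 10⁻³⁰⁰ before logs; exp(G) is clamped at
  e⁷⁰⁰ (a window with such G is dead anyway).
- AIC ties in the Marey complexity search break toward the simpler fit.
- The optimizer tolerances (ftol/xtol/gtol 10⁻¹⁵, profile scan 41 log
  points over α·x ∈ [10⁻⁴, 10⁴]) are chosen so noiseless recovery reaches
  the 10⁻¹² RSS bound.
- Degenerate inputs: all-zero functional density, non-positive sh or P,
  fewer than 20 windows, fewer than 2 markers, single-model weight
  requests and empty test groups all raise with specific messages; empty
  VCF streams yield empty tables.
- α never decomposes into N, Vbp, J₂,₂; no per-base BGS maps, no
  distribution of fitness effects, no use of amino-acid fixation
  locations, no LD-based recombination inference, no phylogenetic
  regression.  Read alignment and genotype calling sit upstream of this
  package.
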