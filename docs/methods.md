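# Methods

This note documents the statistical models, estimators and numerical
choices behind `locuspair`, and what the synthetic-data tests do and do
not demonstrate about real resequencing data.

## Data model

The unit of observation is a *gene segment*: an alignment of directly
sequenced diploid PCR products in which heterozygous positions carry
two-allele IUPAC codes.  Each diploid consensus is expanded into two
haplotypes with a fixed convention (the alphabetically earlier base goes
to haplotype 1).  True phase is unknown from direct sequencing, so any
haplotype-level quantity computed from such expansions (haplotype counts,
haplotype diversity, r²) is *phase-naive*; on synthetic data the phased
haplotypes are available directly and these statistics are exact.
Statistics that depend only on per-site allele counts (S, singletons, θ_W,
π, Tajima's D, shared/fixed classification, F_ST) are unaffected by phase.

Site filtering is complete deletion: any column containing a gap, an N, or
an unresolved ambiguity in any sequence is removed before analysis, and
all reported lengths L refer to the retained columns.  Coordinates are
0-based internally and 1-based in reports.

## Diversity estimators

* S counts columns with ≥ 2 distinct bases; a tri-allelic column counts
  once.  A column contains a singleton when some allele occurs exactly
  once.
* θ_W = S / (a₁ L), a₁ = Σ_{i=1}^{n−1} 1/i.  No finite-sites correction is
  applied; the per-segment values of the study tables are reproduced
  exactly by this uncorrected form.
* π is the mean number of pairwise differences divided by C(n,2) and L,
  with no Jukes–Cantor correction.
* Tajima's D uses the 1989 coefficients
  (b₂ = 2(n²+n+3)/(9n(n−1))); the implementation is pinned against
  Tajima's published worked example (n=10, S=16, k̂=3.888889 → −1.4462)
  and against dendropy's independent implementation.  D is undefined (NA)
  when S = 0; such loci are excluded from cross-locus means and variances
  of D, on observed and simulated data alike — for ABC validity it is the
  *consistency* of this rule across observed and simulated summaries that
  matters, not the rule itself.
* Haplotype diversity is H_e = n/(n−1)(1 − Σ p_k²).
* Synonymous/nonsynonymous site counts follow Nei & Gojobori (1986):
  fractional site counts per codon averaged over haplotypes, and pathway
  counting between codon alleles differing at more than one position, all
  stop-free minimal pathways weighted equally.  When several allele pairs
  disagree on the class of a segregating position the site is split
  fractionally and rounded at the segment level.

## Divergence

Per column (over sites passing the joint filter of both species): shared
(segregating in both), fixed (monomorphic in both, different bases),
private (segregating in one).  F_ST is Hudson's 1 − H_w/H_b with H_w the
unweighted mean of the two within-species mean pairwise difference counts
and H_b the between-species mean pairwise count.  This estimator replaces
the hierarchical AMOVA of the original workflow: it is fast enough to be
used as a per-draw ABC summary, and the permutation test (10,000 label
permutations of whole individuals, both haplotypes moving together;
p = (1+#{F ≥ F_obs})/(n_perm+1)) preserves the significance logic.  Note
that with the unbiased within-species π the estimator equals −1/(n−1)
(not exactly 0) for identical allele frequencies; it is unbiased around 0
under panmixia.

Hardy–Weinberg equilibrium per SNP uses the exact conditional test:
given the allele counts, every compatible heterozygote count is
enumerated with probability
P(het) ∝ n! 2^het / (n_AA! n_Aa! n_aa!), and p sums the configurations no
more probable than the observed one.  The deviation direction (observed
minus expected heterozygosity) is reported alongside; the study's
threshold for reporting is p ≤ 0.01.

## Linkage disequilibrium

r² = D²/(p_A p_a p_B p_b) over phased haplotypes, biallelic sites with
minor allele frequency > 0.05 only, with two-sided Fisher exact tests and
Bonferroni correction over the family of all pairs actually tested in a
dataset.  Distances use gene coordinates, so pairs spanning the A/B
segments of a gene include the inter-segment distance; pairs are never
formed across genes.

The decay fit minimizes Σ (r²_ij − E[r²](ρ·d_ij))² with the Hill & Weir
(1988) sample-size-adjusted expectation

    E[r²] = (10+C)/((2+C)(11+C)) · [1 + ((3+C)(12+12C+C²))/(n(2+C)(11+C))],
    C = ρ·d.

The optimization runs over log₁₀ ρ from a six-point restart grid
(10⁻⁵…1) to avoid the ρ=0 boundary; the reported decay summary is the
distance at which the fitted curve crosses r² = 0.2.  As C → ∞ the
expectation decays to the finite-sample floor ≈ 1/n, not to 0.

## Coalescent simulator

An ms-style coalescent with intra-locus recombination.  Conventions:

* time in units of 4N₀ generations; θ = 4N₀μ and ρ = 4N₀r are per site
  and scaled by the locus length L;
* per-pair coalescence rate 2/x(t) in a deme of relative size x(t);
* per-lineage recombination rate ρ·(span of ancestral material in bp);
  breakpoints inside trapped (non-ancestral) material split lineages as
  in the classical ancestral recombination graph;
* per-lineage migration rate M = 4N₀m between two demes;
* mutations at rate θ per ancestral site per unit branch length,
  infinite sites (every mutation is a new column; positions are drawn
  continuously within the hit site, so output positions lie in (0,1)).

Demographies are piecewise epochs: constant size (neutral), exponential
change x(t) = e^{−αt} backward (growth), a size drop to f·N₀ on
(t_b, t_b+d) with f fixed at 0.02 (bottleneck), and a two-deme split
(sizes 1 and N₂, symmetric migration M, merging at t_s into a deme of
size N_anc), plus the no-split null in which one panmictic deme changes
size to N_anc at t_s while sample labels are retained.

The kernel tracks ancestral material per discrete site as a bitmask of
descendant samples (two 62-bit planes; up to 124 haplotypes), is compiled
with numba, and places mutations on the fly, so no genealogy is stored.
Growth-epoch coalescence times use the closed-form inversion
w = ln(1+αE/A)/α.  Waiting-time competition across event types is exact
within an epoch; epoch boundaries truncate and re-draw.  A fixed seed
gives bit-identical output.  The simulator is validated distributionally
against Watterson's E[S] = θL·a₁, against known demographic signatures
(negative D under growth, haplotype loss under bottlenecks, F_ST
monotone in M), and against msprime run at matched parameters with the
identical summary code.

One deliberate property of Tajima's D surfaced by this calibration: its
finite-sample mean under the standard neutral model is *not* 0 but ≈ −0.09
at n=20, θ_locus=10 (confirmed independently with msprime).  The
calibration suite asserts E[S] to Monte-Carlo precision; a check that the
mean of D lies within ±0.05 of zero fails for this reason and is kept
failing rather than loosened.

## ABC

Single-species summaries: across-locus mean and variance of θ_W, Tajima's
D and the number of haplotypes (6 statistics).  Two-species summaries:
average θ_W, D and haplotype number in each population and combined,
the across-locus mean Hudson F_ST, and the total shared/fixed/private
counts (13 statistics).

Priors follow the study for the single-species models: θ, ρ ~
log-U(10⁻⁴, 1); α ~ log-U(10⁻³, 10); t_b, d ~ U(0, 10); f = 0.02 fixed.
The two-species priors are not printed in the source study ("a relatively
large interval"); this package fixes them once as N₂, N_anc ~
log-U(0.1, 10), M ~ log-U(10⁻³, 10), t_s ~ U(0, 10), with θ, ρ as above.
ρ is defined per site and multiplied by L in each simulation.

Rejection: each summary is standardized by its median absolute deviation
across the simulated table (plain Euclidean distance is scale-dominated;
`none` and `sd` are available as options), degenerate statistics (zero
MAD) are dropped with a warning, rows with undefined statistics get
infinite distance, and the ⌈P_δ·N⌉ closest draws are retained.  The
study's P_δ = 0.001 at 10⁶ draws is the default; the test suite runs
10⁴–10⁵ draws with P_δ = 0.01 so that the accepted-set size stays in the
hundreds.

Regression adjustment is local-linear (Beaumont-style): Epanechnikov
weights on distance, each parameter regressed on the standardized
summaries on its unconstrained scale — log for log-uniform priors, logit
within the bounds for uniform priors — and residuals recentred at the
observed summaries before back-transforming.  A single-hidden-layer
feed-forward network (8 units) is available as `method="ffnn"` with the
same recentring logic but no distance weighting (scikit-learn's MLP does
not accept sample weights); the deterministic local-linear method is the
default.  Rank-deficient designs fall back to rejection-only with a
warning.

Model probabilities: a weighted multinomial logistic regression of the
model label on the summaries, trained on the union of the per-model
accepted sets (balanced classes) and evaluated at the observed point.  A
rejection-proportion estimator is reported alongside; because P_δ per
model would make per-model counts equal by construction, that estimator
uses a single pooled distance threshold instead.

Posterior summaries: the mode is the argmax of a weighted Gaussian KDE
(Silverman bandwidth, 512-point grid) computed on the prior's
unconstrained transform of the draws and back-transformed — on the natural
scale the density of a parameter spanning decades piles up at the sample
minimum.  Credible intervals are equal-tailed weighted 2.5%/97.5%
quantiles.  Unit conversions: N_e = θ/(4μg) and t_years = t_s·4N_e·g,
with μ per site per year and g in years (so split times in years do not
depend on g); reported times are rounded to 2 significant figures.

## Posterior predictive checks

Parameters are resampled from the adjusted posterior with their weights;
each draw re-simulates the full locus set.  The extended summary set is
the across-locus mean and variance of θ_W, π, D, haplotype number and
haplotype diversity (per population for two-population models, plus
per-locus F_ST and shared/fixed/private counts).  Tail probabilities
count ties half: p = (#{sim<obs} + ½#{sim=obs})/n, flagged outside
(0.025, 0.975); the same logic per locus flags outlier loci.  The PCA
check standardizes summaries over the pooled rows, fits two components
per model, and draws the 95% bivariate-normal coverage ellipse of the PC
scores (chi-square(2) quantile 5.991); the observed data are projected
with each model's loadings and classified inside/outside.  A
convex-region alternative was considered and rejected: the ellipse is
deterministic and its coverage is directly testable (0.95 ± 0.02 at
5,000 rows in the suite).

## Synthetic data

The generator emulates the study design: 18 genes, two segments of
300–900 bp separated by 1.5–6 kb (one coalescent simulation spans the
whole gene, so between-segment LD is genealogically consistent), 24
diploids per species, whole-individual segment dropouts at a configurable
rate producing the variable per-segment n of real resequencing tables.
Binary infinite-sites output maps to nucleotides with ancestral base A and
derived base G (all downstream statistics used on synthetic data are
allele-label invariant); SNP positions are rounded to distinct integer bp
with collision re-draw.  Default truth parameters are the fitted values of
the study's split-with-migration model (θ=0.0016, ρ=0.017, N₂=0.8,
N_anc=3.99, M=0.036, t_s=0.44) for two-species designs and θ=0.003,
ρ=0.007 for single-species designs.

What the synthetic data do not emulate: sequencing error, indels (excluded
from analysis by design), paralogous amplification, phasing uncertainty
(synthetic haplotypes are truly phased) and population structure within
species.  Passing tests therefore demonstrate the correctness of the
estimators and the internal consistency of the inference machinery, not
robustness to those real-data artifacts.

## Problem sizes in the test and acceptance runs

The calibration suite uses 10,000 neutral replicates (n=20, θ_locus=10).
The ABC recovery study uses the study's 14-locus layout at reduced scale —
24 haplotypes per locus and 80 bp loci — with one shared reference table
of 10⁵ prior draws, P_δ=0.01, and 20 independent pseudo-observed
datasets; model choice uses 10⁴ draws per model at 12+12 haplotypes.
These sizes were chosen so the full analysis replays in minutes on a
single core while keeping accepted-set sizes in the hundreds; coverage
and model-recovery rates are insensitive to the locus length, which
enters only through the information content of each locus.

## Known limitations

* The coalescent kernel uses discrete recombination breakpoints between
  the L sites of a locus (exact for sequence data of length L; not a
  continuous-locus approximation).
* Phase-naive r² on real unphased input is approximate; the statistical
  phasing used by the original workflow is out of scope.
* The FFNN adjustment ignores acceptance weights (library constraint) and
  its architecture is a fixed small default.
* AMOVA-based F_ST is not implemented; Hudson's estimator is used
  throughout, so absolute F_ST values are not directly comparable to
  AMOVA outputs.
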