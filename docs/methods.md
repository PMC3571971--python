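# Methods

This note documents the models, conventions, and numerical choices behind
`omegascreen`, and what its synthetic-data validation does and does not
demonstrate.

## The codon substitution model

All rate inference is built on a Goldman–Yang-style codon model over the 61
sense codons of the standard nuclear genetic code (stop codons are excluded
from the state space, which is appropriate for nuclear protein-coding
genes). For sense codons i ≠ j,

    q_ij = 0                       more than one nucleotide differs
         = π_j                     synonymous transversion
         = κ π_j                   synonymous transition
         = ω π_j                   nonsynonymous transversion
         = ω κ π_j                 nonsynonymous transition

with κ the transition/transversion rate ratio, ω = dN/dS the
selection-intensity ratio, and π the stationary codon frequencies. Q is
rescaled to one expected substitution per codon per unit time at
stationarity, so branch lengths are in expected substitutions per codon.
The chain is time-reversible by construction; transition probabilities
P(t) = exp(Qt) are computed by symmetric eigendecomposition through the
π^(1/2) similarity transform, with tiny negative entries clamped to zero.

**Codon frequencies.** Default F3x4 (codon frequencies from the
position-specific nucleotide frequencies of the alignment being analyzed);
`equal` and `F61` are available. F3x4 is the conventional default of codon
ML software and the choice matters little for the likelihood-ratio
contrasts the screen relies on.

**Likelihood.** Felsenstein pruning over unique site patterns with
multiplicities; leaves with missing codons contribute all-ones partial
vectors; internal partials are rescaled per pattern to avoid underflow.
Site-mixture likelihoods sum class likelihoods per site with mixture
weights (log-sum-exp).

**Mixture rate normalization.** In the site models (M1a/M2a/M7/M8) the
class rate matrices share a single normalization: branch lengths measure
substitutions per codon *averaged over site classes*, so a class with
ω > 1 genuinely accumulates proportionally more substitutions than a
purifying class. This is the convention of standard codon ML software and
it carries most of the per-site information about positive selection; the
simulator uses the identical convention, and per-branch models use
per-matrix normalization (branch lengths are per-branch expected
substitutions).

**dN/dS decomposition.** With Q scaled to unit flux, a branch of length t
carries t·ρN nonsynonymous and t·ρS synonymous substitutions per codon,
where ρN, ρS are the flux shares of the fitted Q. Dividing by 3·NN and
3·SS — the corresponding shares of the *same* Q evaluated at ω = 1
(mutational opportunity) — gives dN and dS per site, and dN/dS equals the
fitted ω identically. For site mixtures the decomposition is evaluated at
the mixture-mean ω = Σ p_k ω_k, the quantity reported as "mean dN/dS".

## Model fitting

Free parameters (κ, the ω structure, and by default all branch lengths)
are maximized by box-bounded L-BFGS-B with numerical gradients. Bounds:
ω ∈ [1e-4, 999], κ ∈ [0.1, 99], branch lengths ∈ [1e-6, 50], mixture
proportions handled through stick-breaking coordinates in (0, 1), beta
shapes in [0.005, 99]. Each fit starts from an NG86-style counting
estimate of ω and pairwise distances, plus optional random restarts
(`n_starts`, default 4 = informed + 3 random; the genome screen uses the
informed start only, which profiling showed is reliable for the one-ratio
and two-ratio models on data of a few hundred codons). Convergence is the
optimizer's relative-improvement criterion (ftol 1e-12 on −lnL); if no
restart converges the best point is returned flagged.

Degenerate genes (no variable, fully observed codon column) cannot inform
ω: they are returned at the ω lower bound with a `degenerate` flag, never
tested, and never called rapidly evolving.

**Site-model pairs** (M1a↔M2a, M7↔M8) use a two-stage strategy: branch
lengths are estimated once under the one-ratio model, then each site model
optimizes its mixture parameters and κ together with a single tree-length
scale factor. This reduces the expensive dimension from ~20+ branch
lengths to 4–6 parameters; joint optimization is available
(`optimize_branch_lengths=True`) but was slower and no more accurate in
our simulations. The alternative model of each pair is additionally
started from the null's optimum with a vanishing positive-selection class,
which enforces the nesting inequality lnL(alt) ≥ lnL(null) up to optimizer
tolerance. The M1a↔M2a and M7↔M8 LRTs use χ² with 2 df; beta
discretization uses K = 10 equal-probability classes represented by their
conditional means.

## BEB site posteriors

After an M2a or M8 fit, per-site posteriors over ω classes are computed
two ways. NEB plugs in the MLEs. BEB integrates the mixture parameters
over a uniform grid prior (10 points per free dimension: proportions on
(0,1) via simplex midpoints, ω0 on (0,1), positive-selection ω on
(1, 11], beta shapes on (0, 2]) while κ and branch lengths stay at their
MLEs. For M8 the beta-class site likelihoods are linearly interpolated
from the site-likelihood curve evaluated on a fixed ω lattice in (0,1) —
the curve is smooth in ω and NEB never uses the interpolation. Sites with
posterior probability of an ω > 1 class above 0.95 are flagged. BEB is
slightly more conservative than NEB, as intended.

## The genome screen

The mean ω of a gene set is estimated from the concatenation of all its
alignments: a one-ratio fit for the global mean, and for each branch a
two-ratio fit (that branch foreground) whose foreground estimate is the
branch mean. Per gene and scope, the free model is tested against the
model with the relevant ω fixed at the mean (1 df; the fix is in the
parameter interior, so the χ²₁ reference involves no boundary issue).
Storey q-values are computed within each scope family separately, and a
gene is *rapid* only when q < 0.05 **and** its free estimate exceeds the
mean — the screen reports acceleration, not mere deviation. The 4-taxon
screen uses the completely unresolved star phylogeny; candidate-gene site
analyses require a resolved user-supplied tree.

## Expression model

Two-channel dye-swap arrays are normalized by background subtraction,
orientation correction to log2(sexual/vegetative), and per-array median
centering over well-measured spots. *Well-measured* means both channels'
foreground exceeds background on that spot; a gene is analyzable with ≥ 2
well-measured arrays. Per gene, the corrected ratios are modeled as
y_a ~ Normal(μ, σ²) with Jeffreys prior ∝ 1/σ², giving the closed-form
scaled Student-t posterior for μ (df = n−1, location ȳ, scale s/√n, with
s floored at 1e-6 on the log2 scale so replicated identical ratios give
p → 0 rather than 0/0). The reported p is the two-tailed posterior tail
probability 2·min{P(μ>0|y), P(μ<0|y)}; a Gibbs sampler implementing the
same model (with a Rao-Blackwellized interval estimate) serves as a
simulation cross-check of the closed form.

Categories are exclusive and exhaustive over well-measured genes: sexual
(p < 0.05, mean > 0), vegetative (p < 0.05, mean < 0), otherwise
constitutive; p exactly at the threshold is constitutive (strict
inequality). The stringent subcategory flags sexual genes with Storey
q < 0.10. q-values use the λ-grid {0, 0.05, …, 0.90} with a cubic
polynomial smoother evaluated at λ = 0.90, falling back to the λ = 0.5
point estimate below 100 tests; step-up enforcement makes them monotone.

Absolute expression is the mean background-subtracted foreground over
well-measured spots — restricted to the matching tissue channel for
sexual/vegetative genes, over all measurements otherwise.

## Alignment preparation

Per-gene aligned fragments are merged to one consensus row per taxon;
conflicting overlaps are resolved by contig size, then fragment length,
then input order (the precedence among the two quality cues is a declared
convention). Insert columns relative to the reference are removed
(restoring the reading frame), codons containing gaps or ambiguity and
premature stop codons are masked as missing, and a terminal stop codon is
removed without complaint. The 4-taxon screen keeps exactly the codon
columns with a sense codon in every taxon (genes with none are excluded,
with the reason logged); deeper candidate-gene alignments instead drop
columns with data from fewer than half the taxa — exactly half is
retained. Coordinates are 0-based half-open internally, 1-based in logs.

## Category statistics

Bootstrap replicates concatenate 10 genes drawn *with replacement* from a
category (a `replace=False` switch provides the alternative reading of
"randomly chosen") and refit the one-ratio and per-branch two-ratio
models; category contrasts compare replicate distributions of dN, dS or
dN/dS with the two-sided Wilcoxon rank-sum test (normal approximation
with continuity and tie correction; exact enumeration when both samples
have ≤ 10 observations without cross-sample ties), BH-adjusted within
each (metric, scope) family.

Enrichment uses Fisher's exact test; the two-sided convention sums
hypergeometric point probabilities no larger than the observed table's
(the R convention), and a directional alternative is available — note
that the directional tail is what reproduces the published worked
examples on the rapid-gene category counts. r×c class-by-category tables
are decomposed into per-cell 2×2 tests (cell versus rest) with BH across
cells, and expected counts are the usual row×column/total products.

Codon usage is summarized as RSCU (counts normalized by synonymous-family
means; 59 informative codons, single-codon families and stops excluded;
families unobserved in a gene are imputed with the global mean RSCU), and
compared by correspondence analysis — SVD of the standardized residuals
of the profile matrix; per-axis inertias sum to the total chi-square
inertia, and codons unused by every gene are dropped (zero margin, zero
inertia). Expression–rate association uses OLS of the global ω on
absolute expression and on CDS length, overall and per category.

## Synthetic data

The codon simulator draws a root sequence from π and evolves it along the
tree with the model's own transition probabilities, so no stop codon can
arise and simulated frequencies converge to π on long branches. Site
mixtures assign each site's ω once at the root and hold it over the whole
tree (the assumption the site models make), using the shared mixture
normalization described above. Per-gene streams derive deterministically
from (seed, gene index); truth labels are written to separate tables,
never into the FASTA the pipeline reads.

The microarray generator emulates a 4-array competitive hybridization
with two dye swaps: per-gene lognormal baselines (log2 abundance ~
N(10, 1.5)), category-dependent log2 fold changes (gamma-distributed
magnitude with mean `log2_effect`, default 1.5, signed by category, zero
for constitutive genes), channel noise summing to `noise_sd` (default
0.5) on the log2 ratio, additive background around `background_mean`, and
a 2% spot-dropout rate producing not-well-measured spots. Default
category fractions (8.3% sexual, 9.6% vegetative) follow the proportions
observed in the genome-wide experiment the design emulates. The generator
does *not* model print-tip or intensity-dependent dye bias, spatial
artifacts, or cross-species hybridization loss, so passing tests
demonstrate correctness of the inference chain under its own assumptions,
not robustness to those artifacts. Likewise the codon simulator omits
indels, alignment error, and dS variation across genes.

## Validation studies and problem sizes

`omegascreen.studies` (run by `scripts/acceptance.py` and the acceptance
tests) fixes these study sizes: 20 one-ratio recovery refits at ω = 0.2 on
500-codon 4-taxon star alignments; 500 null screen simulations of
300-codon genes at the mean ω = 0.111; two 60-gene categories at ω = 0.14
vs 0.08 contrasted through 100 bootstrap replicates of 10-gene
concatenations; 10 + 10 selection/null replicates of 12-taxon, 400-codon
site-model analyses (ω2 = 5, p2 = 0.1) for BEB site recovery; and the four
oracle contrasts (pruning vs direct summation, Fisher vs exhaustive
enumeration, rank-sum approximation vs exact, Gibbs chain vs analytic
posterior at 50,000 retained draws). The bootstrap replicate count (100)
and the screen analyses restrict to the global scope in these studies;
both are scaled-down but statistically adequate analogues of the
full-scale procedure (1000 replicates, all branch scopes), chosen so the
whole validation suite runs comfortably on a single CPU.

## Known limitations

* The Bayesian expression model is a deliberately simple hierarchical-free
  per-gene model; it reproduces the contract of the cited Bayesian
  analysis (posterior relative expression with 95% credibility) but is not
  a reimplementation of that software's internals.
* BEB here uses the uniform grid prior described above; it approximates,
  but is not numerically identical to, the published BEB procedure.
* dS-rate variation, branch-site models, and amino-acid/nucleotide models
  are out of scope.
* The screen's branch means are taken from two-ratio fits on the all-genes
  concatenation — the natural analogue of the global procedure; the source
  publication does not state its branch-mean construction.
* Numerical equality with published per-gene ω estimates is not expected:
  those depend on deposited expression/EST data and unstated control
  settings; the validation surface is the worked arithmetic plus
  simulation recovery, as documented above.
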