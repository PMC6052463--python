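# Methods

This note documents the models implemented in `longsig`, the defaults and
why they were chosen, the numerical conventions, and what the synthetic
data generator does and does not emulate.

## Normalization

A gene is dropped when **three or more species** have **fewer than 3 raw
counts** (both thresholds configurable); the rule is applied to raw counts
before any scaling, so a gene expressed in only a couple of species never
reaches the cross-species models.

TMM scale factors use the conventional doubly-trimmed weighted mean: per
library vs a reference, M-values (log2 ratios of library-size-normalized
counts over genes expressed in both) are trimmed 30 % on each side,
absolute log2 intensities 5 % on each side, and the survivors averaged
with inverse delta-method-variance weights; factors are rescaled to
geometric mean 1. The reference library is the one whose upper-quartile
normalized count is closest to the mean upper-quartile. The
implementation reproduces Bioconductor edgeR's `calcNormFactors` to
1e-6 on composition-biased matrices (cross-checked in the test suite when
an R installation is present).

log-RPKM is `ln(count * 1e9 / (length_bp * effective_library) +
pseudocount)` with effective library = library size × TMM factor.
Whether the effective or the raw library size enters the RPKM
denominator is a genuinely open choice; effective sizes are the default
and `to_log_rpkm(m, factors=None)` gives the raw variant. The default
pseudocount is 0 — zeros become −∞ and are flagged; the low-expression
filter removes most zero-heavy genes first, and a small ε is available
for synthetic edge cases.

Standardization is per gene: mean 0, sample SD (n−1 denominator) 1.
Constant rows are dropped with a warning. The Shapiro–Wilk QC summary
(`normalcy_fraction`) reports the fraction of genes whose per-row
normality test does not reject at α = 0.05, with no multiplicity
correction — it is a QC descriptive, not an inference.

## Evolutionary covariance models

All regressions assume Gaussian residuals whose species × species
covariance comes from one of four models on the calibrated tree
(branch lengths in million years, My):

- **Null**: σ²·I (independent species).
- **BM**: σ²·t_ij, t_ij = root-to-MRCA shared path length.
- **Lambda**: BM with off-diagonals multiplied by λ ∈ [0, 1].
- **OU** (stationary form): (σ²/2α)·e^(−α·d_ij), d_ij = patristic
  distance. The stationary convention is the common regression default;
  on an ultrametric tree it is the Hansen form with the root conditioning
  absorbed into the stationary variance.

σ² is profiled out of the likelihood in closed form (σ̂² = r'V₀⁻¹r/n);
λ and α are estimated by bounded scalar search (λ ∈ [0, 1];
α ∈ [1e-6, 50/T] with T the tree depth, searched in log space with
restarts; convergence tolerance 1e-8). Slope standard errors use the
unbiased scale r'V₀⁻¹r/(n−p) and a t reference with n−p degrees of
freedom, conditional on the estimated covariance parameters — the common
GLS practice; no correction is made for their estimation. Model ties
within 1e-6 log-likelihood go to the simpler model
(Null < BM < Lambda/OU). Non-positive-definite covariances (possible
with zero-length tie branches) receive a relative diagonal jitter of
1e-10 with a warning.

**Pagel's λ** is the ML λ under an intercept-only lambda-model GLS.
**Blomberg's K** is (MSE₀/MSE) / [(tr V − n/(1'V⁻¹1))/(n−1)] with V the
unit-rate BM covariance and the mean estimated phylogenetically; K = 1
is the BM expectation, exactly so on a star tree.

**Multi-optimum OU (Hansen model).** Branches are painted with up to
three selective regimes from a taxon → group table: a branch takes its
descendant tips' group when unanimous, otherwise its parent's regime; the
root regime defaults to the group on the outgroup side (the smaller root
child). The expectation of tip i is W(α)·θ where the weight of regime r
accumulates e^(−α·(T_i − t)) decay along the root-to-tip lineage, plus
e^(−α·T_i) on the root regime; rows of W sum to 1 identically. The
covariance is the stationary OU form. BM (null) vs OU(k) is compared by
a likelihood-ratio test on χ² with 1 + (k − 1) degrees of freedom (α
plus the extra optima; the BM mean and θ₁ are exchangeable). The
boundary problem at α = 0 is acknowledged: the nominal χ² reference is
used, as in the approach this follows, and an optimizer at the lower
boundary falls back to the BM likelihood. Default regime partitions for
the packaged species: k = 2 splits the two subgenera; k = 3 additionally
splits the melanogaster group from the rest of *Sophophora* — the
finer partitions nest, so the OU log-likelihood is monotone in k.

## Expression phylogram

Distances are 1 − Spearman ρ between species expression profiles
(average ranks on ties — this matters for count-derived values), giving
values in [0, 2]. Neighbor joining uses the Q-criterion with a
deterministic lowest-index tie-break; negative branch lengths are clamped
to zero with the deficit moved to the sibling edge. Gene-bootstrap
support of an internal edge is the fraction of B resamples (genes drawn
with replacement) whose NJ tree contains the same bipartition, ignoring
branch lengths. The bootstrap defaults to standardized expression; the
log-RPKM stage can be passed instead. An outgroup can be named for
display rooting only.

## Divergence plateau

For each unordered species pair, divergence y is the mean over genes of
the two-value sample variance (e_i − e_j)²/2 (denominator 1 — chosen so
y has the pairwise form; divergence is between two species), and x is
the age of the pair's MRCA on the calibrated tree (not half the
patristic distance, although the two coincide on an ultrametric tree).
The fitted model is y(x) = σ²/(2α)(1 − e^(−2αx)) by bounded nonlinear
least squares with 5 log-spaced α starts and RSS tolerance 1e-10; when
the best α falls below 1e-6 the closed-form BM line y = σ²x is reported
with α = 0. Percentile 95 % CIs come from B gene-bootstrap refits
(failed refits dropped and counted); the jackknife removes one species
at a time and reports the (min, max) refitted α.

**Recovery experiment.** The packaged recovery experiment simulates
genes as i.i.d. stationary-OU draws on the 14-taxon fixture tree (so
E[(e_i − e_j)²/2] follows the model curve exactly), computes the 91
divergence points, and refits. Rows are emitted on the standardized
scale directly — their stationary variance σ²/(2α) ≈ 1.055 at the
default parameters already matches standardized data — and are *not*
re-standardized per row: dividing each 14-species row by its own sample
SD would change the generating process (E[1/s²] ≠ 1/E[s²] at n = 14)
and the experiment is meant to test the fitter against the model it
fits. Defaults: 6,510 genes, 20 replicates, α = 0.0673/My,
σ² = 0.142/My.

## PGLS longevity signature

Per gene, standardized expression is regressed on the log-transformed,
standardized trait (median lifespan in days by default; body mass in mg
accepted as an alternative single predictor) under the four covariance
models, with λ/α estimated jointly with the coefficients by ML. The best
model is the raw maximum-likelihood winner — not AIC — matching the
procedure this implements; the signature is ranked by the winner's slope
p-value, with Benjamini–Hochberg q-values and the slope sign. Expression
is the response and the trait the predictor: the residual-covariance
models describe species-level expression residuals. With an exclusion
list (e.g. the long-lived outgroup species) the regression is repeated
on the remaining species and the fraction of baseline hits still at
p < threshold is reported.

**Known property: model selection inflates the realized type-I error.**
With the true covariance supplied, the slope t-test is exactly calibrated
(measured 4.9 % at nominal 5 %). Selecting the best of four models by ML
and then reading the winner's p-value is mildly anti-conservative at
n = 14 species: on null synthetic data the realized rate is ≈ 6–9 %
depending on the trait realization (genes for which a misspecified BM
covariance happens to fit best contribute most of the excess). This is
a property of the published-style procedure itself, not of the
implementation; calibration checks therefore average over several
independent trait draws. How body mass was jointly accounted for in the
motivating analysis is not specified there; only single-predictor fits
are implemented.

## Direction concordance

Matches are counted over the gene intersection: positive correlation ↔
up-regulation under a lifespan-extending intervention (or pro-longevity
annotation), negative ↔ down (or anti-longevity). Significance is the
exact one-sided upper binomial tail P(X ≥ k_same | n, ½). The sidedness
was resolved by derivation: only the upper tail reproduces all printed
reference rows, including a 47 %-matching experiment with p ≈ 0.82
(a two-sided or lower-tail convention would give ≈ 0.21). The
permutation variant shuffles the signature's sign labels without
replacement, recomputes the binomial tail per replicate, and reports
(1 + #{p ≤ p_obs})/(B + 1) so no p-value is exactly zero. The percent
column rounds half away from zero. Curated "necessary for fitness"
annotations (deletion shortens lifespan) count as pro-longevity.

## Synthetic data generator

The generator encodes the statistical structure the analysis assumes —
not fly biology (no real generative process for these species is known).
Defaults are the study conditions: 14 species, 56-My tree depth, 6,510
genes, OU selection 0.0673/My and drift 0.142/My (the fitted plateau
parameters), ~5.9 % signature genes (384 of 6,510 hits), an 85/15 OU/BM
gene mix (the observed OU-preference fraction), target signature
R² = 0.8, DE direction agreement q = 0.63 (the middle of the observed
58–69 % range), lifespan optimum 25 days and mass optimum 1 mg (the
middle of the observed ranges), and library sizes of 15–30 M reads with
gene lengths of 0.5–5 kb — typical bulk RNA-seq scales.

Trees are pure-birth (Yule) with all branch lengths rescaled so the root
depth hits the target — the simplest ultrametric process with an exact
depth calibration. Log-lifespan is a stationary OU draw around the log
optimum, so its cross-species spread is σ²/(2α) (≈ 1.06 at the
defaults, giving roughly a sixfold lifespan range); log-mass shares the
dynamics at a smaller scale with a positive coupling to lifespan.
Signature genes are b·L + √(1 − b²)·η with b = ±√(effect size), L the
standardized log-lifespan and η a standardized tree-structured draw from
the gene's own model — the residual has the same phylogenetic structure
as null genes, so PGLS assumptions hold by construction. Counts are
Poisson around exp(log-RPKM)·(length/10³)·(library/10⁶) — species means
here are single libraries, so biological dispersion is carried by the
evolutionary layer; an optional gamma overdispersion switches to a
negative binomial. Every generator is a pure function of (inputs, seed);
one root seed spawns independent per-operation streams.

What the generator does **not** emulate: tissue heterogeneity,
sequencing reads, multi-replicate designs, batch effects, ortholog-call
errors, or survival data. Passing tests therefore demonstrate that the
estimators recover the structure they assume, not that real fly data
satisfy that structure.

## Problem sizes in tests

The packaged checks run at: 20 × 6,510-gene replicates for plateau
recovery; 200-replicate Pagel-λ recovery and 400-gene Blomberg-K
calibration; 200 genes for the 2-regime OU classification; 4 × 400-gene
null draws and one 300-gene power draw for the PGLS calibration/power
checks; 40-replicate bootstraps for phylogram support. These sizes keep
Monte-Carlo error comfortably inside the asserted tolerances.

## Known limitations

- n = 14 species bounds the power of every per-gene inference; the
  motivating analysis found no gene passing FDR < 0.05 either.
- The χ² reference for the BM-vs-OU LRT ignores the α = 0 boundary,
  making the classification slightly liberal.
- The OU regression covariance is the stationary form; the
  non-stationary Hansen conditioning is not exposed for the
  single-optimum regression models.
- Percentile bootstrap CIs are first-order; no BCa correction.
- The concordance tests treat external DE direction calls as given;
  DE calling itself is out of scope.
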