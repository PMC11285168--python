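# Methods

This note documents the models and procedures implemented in `tpod`, the
defaults and why they were chosen, what the synthetic-data generator does and
does not emulate, and the numerical choices that matter for reproducing
results.

## Study design

The pipeline targets dose-series bulk RNA-seq from an exposure experiment: a
vehicle (carrier) control plus a geometric dilution series whose top
concentration is the compound's EC20, so that transcriptomic sampling stays
below overtly phenotypic exposure. Defaults follow that design: dilution
factor 10, three dilutions below the anchor (five concentrations including
control), three biological replicates per concentration. The number of
dilution steps is configurable; three is a common 96-well layout and keeps
the series within three decades. Concentrations are carried in µM everywhere;
log10 transforms are computed at use sites and never persisted.

## Synthetic data generator

Each gene has a baseline expected count (lognormal across genes, median ~100,
log-sd 1.2 by default), a negative-binomial dispersion φ (variance
µ + φµ², default 0.05), and a response curve giving the shift of log2 mean
expression as a function of concentration. By default 10% of genes respond,
split evenly across three shapes: Hill (sigmoidal), saturating exponential,
and linear. Linear curves saturate at the gene's drawn amplitude: an
unbounded line solved to cross the benchmark response at a low concentration
would imply astronomically large means at the top dose, which no real
transcript does; the curve is exactly linear through the region where the
benchmark dose lives. Amplitudes default to 1–3 log2 units at saturation,
i.e. roughly 3–9 noise SDs at φ = 0.05 — sparse, strong signal, the regime of
a low-DEG compound; denser or weaker signal is a parameter away.

Responsive genes are assigned target true benchmark doses either log-uniform
over the tested nonzero range or from a Gaussian mixture on the log10 axis
(used to plant clustered BMD structure); curve scale parameters are solved in
closed form so that the curve crosses the generator's benchmark response
exactly at the target. `true_bmd_of` is the oracle used for recovery scoring:
a bracketing scan plus root refinement of |curve(c) − curve(0)| = BMR,
validated in tests against a dense-grid search.

Counts are drawn per sample with expected values rescaled so each column's
expected total equals that sample's library size (lognormal depth jitter,
σ = 0.1). This rescaling makes the data compositional in the same sense real
sequencing is — a strongly induced minority of genes slightly depresses
everyone else — which is exactly what median-of-ratios normalization is meant
to absorb. Each gene draws from its own counter-based RNG stream keyed by
(seed, gene index), so identical seeds reproduce matrices bit-for-bit.
Defaults simulate ~0.2 M reads/sample: the real assay's ~12 M reads scaled
down so tests run in seconds; per-gene counts at the default gene numbers are
comparable to a moderately expressed transcriptome slice.

What the generator does not emulate: gene length and GC effects, correlated
co-regulation between genes, outlier samples, batch structure beyond an
exchangeable replicate label, and multi-modal (non-monotone) dose responses.
Passing recovery tests therefore show the statistics behave as designed under
clean NB noise, not that they are robust to every pathology of real data.

## Differential expression

Median-of-ratios size factors (geometric-mean reference over genes positive
in all samples, factors rescaled to geometric mean 1) feed both a
log2(count/factor + 1) normalized matrix for the trend/BMD stages and an
offset for the per-gene negative-binomial GLM. The DE contrast is top
concentration vs control with design `~ replicate + condition`.

Dispersion is estimated per gene by method of moments around the group
means, a trend φ(µ) = a₀ + a₁/µ is fitted across genes, and gene-wise values
are shrunk toward the trend on the log scale with a prior weight equivalent
to six residual degrees of freedom. The Wald statistic for the condition
coefficient is referred to a Student-t with (moment df + prior df) degrees
of freedom, the moderated-t logic: simulation at 3 vs 3 replicates shows the
plain normal reference is mildly anticonservative (null rate ~0.07 at
nominal 0.05) and the raw residual-df t is badly conservative (~0.002);
the moderated reference sits at ~0.04. DEGs are genes with BH-adjusted
p < 0.05 and |log2FC| ≥ log2(1.5) = 0.585. This stage is intentionally a
simplified NB-GLM, not a DESeq2 clone: no Cox–Reid adjustment, no LFC
shrinkage, and exact concordance with DESeq2 is not promised.

## Williams trend prefilter

Genes entering dose-response modeling must show a monotone trend and at
least a 1.5-fold change. Williams' statistic compares the isotonic
(pool-adjacent-violators) amalgamation of the dose-group means at the top
dose with the control mean, scaled by the pooled within-group variance.
Instead of Williams' published critical-value tables, significance comes
from a permutation null (labels permuted across all groups), which is exact
at three replicates per group and needs no table interpolation. Both
directions are tested; the direction with the larger |t| is kept and its
one-sided permutation p is Bonferroni-doubled. The p threshold is 0.05 (the
common prefilter convention; the fold-change gate of 1.5 is applied to
linear-scale group means vs control). Default 10,000 permutations for
single-gene use; the matrix driver shares permutations across genes, and
1,000 permutations are ample for a 0.05 gate (p resolution 1/1001).

The vectorized per-row isotonic fit uses the exact minimax characterization
(max over left segment ends of min over right ends of segment weighted
means), not iterative pooling; tests verify it against both the scalar PAVA
stack algorithm and a brute-force search over monotone block partitions.

## Dose-response suite and benchmark dose

Eight continuous models are fitted to each prefiltered gene's log2
normalized expression under homoscedastic Gaussian error: linear, quadratic,
power, Hill, and four nested exponential forms (exp2–exp5: exponential
growth/decay, its shape-power generalization, saturating exponential with an
asymptote, and its shape-power generalization). Power/Hill/shape exponents
are bounded to [0.5, 18]; every model evaluates to its background at
concentration 0. Nonlinear models are parameterized in the scaled dose
c/cmax, which makes fits exactly equivariant under rescaling of the
concentration axis (tested). Third- and fourth-degree polynomials are
excluded: with at most five dose groups they are barely identifiable and
produce wild extrapolations.

Fits use deterministic multi-start: a fixed grid over the genuinely
nonlinear parameters with the background (and any linear-in-parameters
scale) profiled analytically, then bounded nonlinear least squares from the
best grid point. The nested exponentials are additionally seeded with the
lower member's solution, so the richer model's likelihood can never fall
below the nested one's.

The best model is chosen by AICc (AIC with the small-sample correction),
with ties broken by fewer parameters and then a fixed model order. With ~15
observations and up to five parameters plain AIC systematically over-selects
flexible models; in simulation this costs about five percentage points of
median relative BMD error, so the corrected criterion is the default (plain
AIC remains available and is reported).

The benchmark response is `bmr_factor` × the control-period noise SD on the
log2 scale, default factor 1.0 (1.349 and other conventions are a parameter).
The noise SD is the best model's residual SD, moderated across genes
empirical-Bayes style (log-variance trend on mean expression, prior df 4):
a single gene's residual SD at 15 observations is noisy enough to dominate
BMD error otherwise. The BMD is the smallest positive concentration where
the fitted curve departs from background by the BMR, found by bracketed root
search on (0, 10 × cmax].

BMDL/BMDU are 90% two-sided profile-likelihood bounds (95% one-sided BMDL,
the usual convention): the model is reparameterized so the BMD is a free
parameter (the constraint f(BMD) − f(0) = ±BMR eliminates one parameter
analytically per model), the profile deviance n·ln(RSS(b)/RSŜ) is traced by
geometric stepping with warm-started reduced fits, and each bound is the
χ²₁ 90% crossing located by root refinement. A side that never crosses
within the search box [10⁻⁶, 10] × cmax is set to the box edge and flagged
`boundary`. If profiling fails the code falls back to a parametric-bootstrap
percentile interval (2,000 refits), flagged `bootstrap`; tests verify the two
routes agree on well-behaved genes.

## Postfilter and tPODs

Gene records are dropped when BMDU/BMDL > 40 (unstable fit), when the BMD
exceeds the highest tested concentration (extrapolation upward), or when it
falls more than 10-fold below the lowest tested nonzero concentration
(extrapolation downward). The filter is idempotent and applied before any
summary.

Two transcriptomic points of departure summarize the retained BMD
distribution. tPOD(10th) is the linear-interpolation (type 7) 10th
percentile. tPOD(mode) comes from a Gaussian KDE of log10(BMD): Silverman's
rule bandwidth by default (scalar override available), 512-point grid over
the data range ± 3 bandwidths; modes are strict local density maxima
(peaks below 5% of the global maximum are discarded as grid noise),
antimodes are the density minima between consecutive modes, and tPOD(mode)
is 10^(lowest mode). The first-mode gene set — the input to
sensitive-pathway enrichment — is every retained gene with log10(BMD) below
the first antimode; with a unimodal density it is all retained genes,
flagged as such. Mode detection requires at least five retained BMDs.

## Enrichment

A generic over-representation analysis against user-supplied GMT
collections: each set is intersected with the universe (by default all genes
tested for DE, the standard background correction), sets larger than 1,000
genes are excluded from testing and reporting, the one-sided hypergeometric
upper-tail p is computed per term, and BH adjustment at FDR 0.05 flags
significance. No live ontology retrieval is attempted; curated term lists
are version-dependent and out of scope.

## Behavior metrics

Tracking tables are neutral per-minute CSVs (larva, bin start, distance,
mean x/y in well-centered mm, phase). The arena is a circular well (10 mm)
with a centered 6 mm inner zone — 36% of the area — and the metrics are:
baseline distance (last 5 light minutes), light→dark startle delta (first
5 dark minutes minus the preceding 5 light minutes), and inner-zone
cumulative duration as a percent of the first dark phase, with occupancy
decided by the radial position of each bin's mean position (sub-bin
excursions are not modeled). Group comparisons use one-way ANOVA plus
Dunnett many-to-one contrasts against the control (multivariate-t based,
seeded); if a group has zero variance the code falls back to rank-based
comparisons with Holm adjustment, with a warning.

## Problem sizes and known limitations

Default test and demonstration sizes are scaled to a desk: 300–5,000 genes,
0.1–1 M reads/sample, 1,000-permutation trend tests, 20 simulation
replicates for DE error control, 500 simulations for familywise-error
checks. These sizes give Monte-Carlo error well below the effect sizes being
checked.

Known limitations: BMD point estimates at three replicates per group and
10-fold concentration spacing carry an irreducible error of roughly a factor
of 1.5–2 around the truth (profiled intervals reflect this); an oracle
given the true model family and true noise SD performs only marginally
better in simulation, so tighter recovery requires more replicates or closer
dose spacing, not different software. The DE stage is not a DESeq2
re-implementation and will not match its output gene-for-gene. Mode
detection inherits KDE bandwidth sensitivity; with few retained BMDs the
antimode boundary is unstable, which is why the first-mode set is flagged
when the density is unimodal.
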