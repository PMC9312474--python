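# Methods

This note documents the models the package implements, the choices made
where the design was genuinely open, and what the synthetic-data tests do
and do not establish about real surveys.

## Data model and counting metrics

An observation is one pass of one transect by one observer.  Detections
carry on-screen intervals `[t_start, t_end]`; **MaxCount** sums individuals
over all events of a pass, **MinCount** (MaxN) is the interval-stabbing
maximum of simultaneously visible individuals, computed exactly by
scanning event starts (with closed intervals the maximum is attained at a
start).  MinCount ≤ MaxCount always.

**Distance windows.**  Observers aim for constant swimming speed, so an
event's along-transect position is `d = (t_start / duration) · length`.
Re-analysing a 50 m recording at 40/30/20/10 m keeps events inside the
central windows (5,45), (10,40), (15,35), (20,30); windows are closed
intervals and events are windowed by their start time (the start is when
the identification was made; midpoint or full-containment rules would
shift borderline events only).

**Transforms.**  Fourth root, log(1+y) (counts contain zeros, so the
logarithm needs the +1 offset), presence/absence, identity.  Shannon
diversity uses the natural log by default (`base` is configurable); an
all-zero or single-species row has H = 0.

## Synthetic studies

The generator draws, per species, a latent log-abundance
`η = base + island + u_loc + u_tr + u_obs + u_obs:loc + u_obs:tr + ε`,
with independent Gaussian random effects at the variances of the
configuration and ε an AR(1) series (marginal variance σ²_residual,
per-species ρ) across the 18 ordered passes of each transect.  True
abundance is COM-Poisson(e^η, ν_s); structural zeros knock out whole
(species, location) combinations; detection is binomial thinning at
`d_s · (1 − sensitivity · turbidity)` with the order effect γ_s tilting
the detection log-odds per pass (negative = deterred, positive =
attracted).  Schooling species get a gamma clump multiplier (shape k,
mean 1) on the rate plus clumped detection events, which is what drives
MinCount visibly below MaxCount.  The rate is capped so the implied
expected count never exceeds ~800 individuals per pass — latent spikes
would otherwise imply absurd school sizes (and unbounded pmf series).

Default conditions: the study design (2·5·3·3·6 = 540 passes), 36
species, exactly one third of them underdispersed (ν > 1), variance
components (0.40 location, 0.25 transect, 0.02 observer, 0.05
observer:location, 0.10 observer:transect, 0.30 residual on the log
scale) chosen so spatial structure dominates observer bias while the
sampling share stays substantial; 15 % of species deterred and 15 %
attracted at |γ| = 0.15 log-odds per pass, 20 % with ρ = 0.4, 20 %
schooling — no quantitative field estimates of these reaction rates
exist, so they are order-of-magnitude choices, stated here once and not
tuned.  Observers cover a transect back-to-back in blocks of six passes;
the block order rotates across transects so observer identity is not
confounded with temporal position.  Randomness uses one root
`SeedSequence` with a child stream per species (design-level draws in
child 0), so adding species never reshuffles earlier species' draws.

What the generator does **not** emulate: spatially explicit fish
movement, within-pass habitat gradients (the time→distance map is exact
by construction, unlike real swimming), species interactions, and
day/tide effects.  Passing tests therefore show the *estimators* behave
correctly under the assumed hierarchical structure, not that real
surveys satisfy that structure.  Under the defaults the per-pass noise in
species density is fairly aggressive, so its sampling share comes out
higher than a calm field survey would show.

## Independence diagnostics

The per-transect ACF uses the full-series mean and denominator (biased
estimator); a constant series is flagged undefined, never silently zero,
and per-lag averages skip undefined transects.  The order-effect model is
a mixed logistic regression (presence ~ order, Gaussian random intercept
per transect) fitted by maximum likelihood with 21-node Gauss–Hermite
quadrature over the scalar random effect; order is centered for
stability.  Wald p-values come from a central-difference Hessian; when
the variance estimate sits at its zero boundary the flat log-σ direction
is dropped from the inversion.  Complete separation (all-present series,
or |β̂| > 10) is flagged and the Wald p reported as uninformative rather
than fabricated.  A likelihood-ratio test was considered and not added:
the Wald test is what single-p-value-per-species reporting implies.

The partial Mantel correlogram uses within-transect pairs only (pairs
from different transects have no temporal order), residualizes both the
dissimilarities and the per-lag indicator matrices on transect-membership
and observer-pair dummies, and correlates the residuals.  The sign is
flipped to the correlogram convention: positive at lag k means passes k
steps apart are *more* similar than average.  Significance is by
permutation of the order labels within each transect, `p = (b+1)/(m+1)`,
Holm-corrected across lags; lag classes with fewer than two pairs are
skipped.

## Pooling (design error)

Within each level of the chosen factor, two *disjoint* subsets of k
passes are drawn without replacement (a shared pass would bias the
dissimilarity toward zero), raw counts are averaged within subsets,
fourth-root transformed, and compared with Bray–Curtis.  Pooling before
versus after the transform is a real ambiguity; transform-after-pooling
is the default (pooling operates on abundances), the other order is
behind a flag.  Histograms use bin width 0.05 on [0,1]; the averaged
histogram is the bin-wise mean over levels.  Dissimilarities equal to 1
are counted as uninformative; pairs where both pooled profiles are empty
are undefined and counted separately, never imputed.

## Univariate variance partitioning

For the balanced design, variance components are estimated by equating
observed mean squares to their expectations from the Cornfield–Tukey
auxiliary table (restricted-model convention) and solving the triangular
system — the ANOVA method of moments, which coincides with REML under
balance whenever all estimates are interior.  The mixed model has Island
fixed; Location (in Island), Transect (in Location), Observer,
Observer:Location and Observer:Transect random.  Raw signed estimates are
kept; negatives are truncated to zero before the ICC, which requires
non-negative shares:

    ICC_r       = σ²_r / (Σ σ²_r + σ²_ε)
    ICC_Total   = Σ ICC_r,   ICC_ε = 1 − ICC_Total
    ICC_Sampling = ICC_ε + ICC_Observer:Transect + ICC_Observer:Location

These identities hold exactly and are property-tested to 1e-12.

**Count models.**  Per-species counts are fitted with a zero-inflated
COM-Poisson GLMM: log link, the same random structure, a single
intercept-only logit for the zero-inflation π (no covariate structure is
justified for the zero part), and ν the dispersion shape (ν < 1 over-,
ν > 1 underdispersed; ν = 1 is exactly Poisson).  The marginal likelihood
uses a Laplace approximation over the full random-effect vector: an inner
Newton solve for the joint mode with analytic η-derivatives (E[Y] and
Var[Y] from the truncated pmf series, with the zero-inflation mixture
handled analytically at y = 0), an outer L-BFGS-B over fixed effects, log
variances, log ν and logit π, warm-started at the Poisson solution.
Poisson and NB2 families share the machinery so AICs are comparable; no
frequentist GLMM fitter for these families exists in the installed Python
stack, so this fitter is part of the package, cross-checked against R's
lme4 for the logistic case.  ICC for GLMMs is computed on the latent
(link) scale, as is standard for glmmTMB-style variance partitioning.
Fits report convergence, variance-boundary and shape-boundary flags; a
species whose counts are almost all zero yields a flagged boundary fit,
not a crash.

**COM-Poisson numerics.**  log Z(λ, ν) is a log-sum-exp over series terms
`y·logλ − ν·log y!`, truncated adaptively once post-mode terms fall below
1e-12 of the running maximum (cap 10⁴ terms; hitting the cap raises a
numeric error rather than returning a truncated constant).  Sampling is
by CDF inversion of the same series.

## Multivariate variance partitioning

Dissimilarities: Bray–Curtis `Σ|x−y|/Σ(x+y)`; Euclidean; Gower as the
mean over species of |x−y|/range with zero-range species contributing 0;
quantitative Kulczynski `1 − ½(Σmin/Σx + Σmin/Σy)`.  The exact Gower and
Kulczynski variants are a free choice; these formulas are the common
quantitative forms and are documented here.  Pairs of all-zero rows are
undefined for the [0,1] indices: flagged, set to 0 (identical empty
assemblages), never dropped silently.

PERMANOVA partitions `tr(H_T G)` where G is the Gower-centered
`−½ J D² J` and H_T the orthogonal projection of each term of the
balanced design (projection traces equal the degrees of freedom; the
partition is exact to 1e-8 against classical ANOVA on Euclidean
single-variable instances, term by term).  Pseudo-F denominators are the
mean-square combinations implied by the expectation table (quasi-F such
as `MS_Loc + MS_Isl:Obs − MS_Loc:Obs` for Island where no single mean
square matches).  Components of variation solve `E[MS] = C·σ²`; the
signed square roots σ′ are reported (negative estimates keep their sign),
while percentage shares truncate negatives to zero before normalizing —
the non-truncated alternative is a flag away.

**Permutation p-values** use Freedman–Lane permutation of the reduced
model's residual matrix `R G R`, with individual observations permuted
within the strata given by the tested term's nesting parents (locations
permute within islands, and so on).  Whole-block exchangeability schemes
per term exist but are not implemented; the residual-permutation scheme
is exact for the one-way case (verified against exhaustive enumeration)
and standard practice for complex designs.  `p = (b+1)/(m+1)`; tiny
instances can enumerate all within-strata relabelings exactly.

**Sweep.**  5 lengths × 2 metrics × 3 transforms × 4 dissimilarities =
120 models; goodness-of-fit is the uncorrected total R² (ratio of
grouping-factor sums of squares over total), and parameter levels are
compared by pairwise paired t-tests over the shared configurations with
Bonferroni correction.  Permutations are skipped in the sweep by default:
R² needs none.

**PCO / CAP.**  PCO is classical scaling of the centered matrix;
negative-eigenvalue axes are reported but excluded from scores.  CAP
fits a linear discriminant analysis on the first m PCO axes (default
m = 8, optionally chosen to maximize LOO accuracy) and classifies each
left-out observation — projected by Gower's add-a-point formula using
the retained axes — to the nearest group centroid in canonical space.
With semi-metric dissimilarities the add-a-point projection is an
approximation on the positive subspace; m is clipped to the available
positive axes with a warning.

## Precision

Univariate precision subsamples k of the 18 passes per transect without
replacement (bootstrap with replacement behind a flag), computes
`(sd/√k)/mean` per draw, averages draws then transects.  Draws whose
subsample mean is zero are excluded *and counted* — the ratio is
undefined there and silent NaN-dropping would bias curves for rare
species.  Confidence intervals use the pooled standard deviation of the
per-draw estimates across transects divided by √(number of transects).
Swim-distance comparisons align (length, repeats) pairs on
`distance = k·length` and flag the minimizing configuration, reporting
exact ties as ties.  Turbidity stratification ranks transects by grade
(stable order breaks ties) into three equal groups.

multSE subsamples the same way, fits the reduced model (Island fixed,
Location and Transect nested random, no observer factor) and reports
`√(MS_residual/k)`; on a single Euclidean variable this equals the
classical `√(MS_within/k)` exactly.  Defaults of 10⁴ draws match
survey-analysis practice; tests and the acceptance script use 10²–10³,
which changes Monte-Carlo error, not structure.

## Problem sizes used in the automated checks

Unit and property tests run on a reduced design (2 islands × 2 locations
× 2 transects × 3 observers × 3 repeats, 72 passes) where the full one
adds nothing; recovery checks that depend on sample size (COM-Poisson ν,
LMM components, Mantel power) run at the full 540-observation design
with 4–50 replicates, and the acceptance script simulates one full study
and runs every stage on it with 100–500 Monte-Carlo draws per quantity.

## Known limitations

* Unbalanced designs are rejected (`DesignError`); the expected-mean-
  squares algebra implemented here is for balanced layouts only, which is
  also why the video-analyst factor is supported only as a crossed factor
  on balanced synthetic data.
* The order-effect model's Wald p is conservative near variance
  boundaries; separation is flagged rather than resolved (no Firth
  correction).
* CAP's leave-one-out loop recomputes the PCO per held-out point
  (exact, O(n) eigendecompositions); at 540 observations this costs
  ~20 s.
* The pipeline's per-species GLMM stage is deliberately not run over all
  36 species by default — at roughly a second per species-family fit it
  is available through the API where needed.
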