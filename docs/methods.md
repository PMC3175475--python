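# Methods

`clinezone` analyzes one-dimensional hybrid zones between two diagnosably
distinct taxa (labelled E and K throughout, after the *eschscholtzii* and
*klauberi* forms of the *Ensatina* salamander ring species whose Palomar
Mountain contact the package models). Input is a per-individual table of
coordinates, habitat covariates and diagnostic-marker genotypes; every
marker is assumed fixed for alternative alleles in the two parental taxa,
so the ancestry of each allele copy is unambiguous.

## Transect projection and orientation

Sampling coordinates are mapped to a local planar frame by an
equirectangular projection (east = R cos(lat0) dlon, north = R dlat,
R = 6371.0088 km). For a study area a few kilometres across the projection
error is well under a metre, so no geodesic machinery is used. The 1-D
transect position at compass heading theta is east sin(theta) +
north cos(theta); the default origin is the coordinate centroid, which
centers positions but makes *absolute* center estimates origin-dependent —
only center differences (e.g. mtDNA minus nuclear consensus) are
comparable across analyses, and the simulation-recovery tests therefore
project in the generator's own frame.

The maximum-likelihood heading maximizes, over a 1-degree grid on
[0, 360), the summed log-likelihood of per-locus *monotone* clines: the
isotonic (pool-adjacent-violators) fit of allele frequency against
position under binomial weighting. The weighted least-squares isotonic
solution and the binomial-ML monotone fit coincide (both are Bregman
projections with the same pooling rule), so the fit is delegated to
`scipy.optimize.isotonic_regression`; tests verify the log-likelihood
against an exhaustive dynamic-programming search over monotone sequences
on a 0.001 frequency grid. Each locus is allowed its better of an
increasing or decreasing cline at each heading, making the profile
180-degree periodic; headings are reported with the convention that
K-allele frequency increases along the positive axis. A golden-section
refinement sharpens the grid argmax.

The heading's two-unit support set (all headings within 2 log-units of the
maximum) is reported, with a caveat established by simulation: because the
monotone fit re-adapts at every heading, the profile is optimistic, and
the support set's half-width (~2 degrees at n = 335 with four loci) is
smaller than the heading MLE's sampling standard deviation (~3.3 degrees).
The support set should be read as a relative-likelihood summary, not a
confidence interval; tests assert recovery of the true heading by the MLE
rather than coverage by the support set.

## Parametric clines

Allele frequency along the transect follows the tanh cline
p(x) = (1 + tanh[2(x - c)/w])/2, with center c (the 0.5 crossing) and
width w (inverse of the maximum slope; dp/dx at c is exactly 1/w).
Per-individual K-copy counts are modelled as binomial draws — 2 trials for
diploid nuclear loci (Hardy-Weinberg within site; no site-level inbreeding
parameter, disequilibrium being handled separately), 1 trial for the
mitochondrial marker — with the binomial coefficient omitted as
parameter-free and p clamped to [1e-12, 1 - 1e-12]. Optimization is
bounded L-BFGS-B on (c, log w) from five deterministic starts (c at the
position quartiles, w at 0.5x/1x/2x a quarter of the span), log-likelihood
tolerance 1e-8.

Uncertainty comes from profile likelihood: the nuisance parameter is
re-optimized at each probed value and the two-unit support limits (the
analogue of a 95% confidence interval; per-parameter coverage is ~95.45%
if the profile is near-quadratic) are located by outward expansion plus
Brent root-finding on profile(theta) - (max - 2). Simulation at n = 300
confirms ~94% per-parameter coverage.

Coincidence (shared center) and concordance (shared width) across loci are
likelihood-ratio tests: the free model fits (c, w) per locus, the
constrained model shares the named parameter, G = 2(LL_free - LL_shared)
is referred to a chi-square with df = (loci - 1) x shared parameters.
Under clean simulated nulls the coincidence test rejects at 0.056
(500 replicates, alpha = 0.05). Stepped and tail-introgression cline
models are deliberately not implemented.

## Hybrid-index concordance

An individual's hybrid index HI is its fraction of K-derived allele copies
(2 per nuclear locus, 1 for mtDNA; missing loci drop out of numerator and
denominator). Barton's concordance model for a focal locus predicts the
per-locus index as HI + He [alpha + beta (2 HI - 1)] with
He = 2 HI (1 - HI): alpha (directionality) shifts the locus toward one
genetic background, beta (abruptness) steepens or flattens its transition.
He is taken literally per individual, so parentals (HI = 0 or 1) carry no
information. Fitting is binomial ML on the per-individual K-copy counts at
the focal locus (not least squares on the scatter — ML remains valid for
the 1-copy mitochondrial marker), with the prediction clamped to
[1e-6, 1 - 1e-6] because large |alpha|, |beta| can push it outside [0, 1].
The regressor HI includes the focal locus by default (a leave-one-out flag
exists). A G-test against alpha = beta = 0 with df = 2 gives the
equal-introgression verdict.

## Disequilibria in a sliding window

Three components, each the statistical association of K-state across
marker copies and bounded in [-0.25, 0.25], positive when K alleles
co-occur:

- within-locus: heterozygote deficit, the plug-in ML estimate
  P_hat(KK) - p_hat^2;
- between nuclear loci: gametic D = h_KK - p_A p_B, with double-
  heterozygote phase resolved by EM on the four haplotype frequencies
  under random union of gametes. The EM runs from the linkage-equilibrium
  start plus eight D-offset starts (±0.02, ±0.1, ±0.2, ±0.24 clipped to
  the feasible range) to escape the saddle at D = 0, stops when the
  log-likelihood improves by less than 1e-10 (monotonicity asserted), and
  a tie between mirror-image optima (within 1e-6) returns 0 with a
  degeneracy flag. Tests check the estimate against a brute-force grid
  search (D step 0.001, margins perturbed around the observed values).
- cytonuclear: each individual is one mitochondrial copy paired with its
  two nuclear copies; the ML estimate is closed-form,
  D = [2 n(K,KK) + n(K,KE)]/(2N) - p_mt p_nuc, because the likelihood
  factorizes (no phase ambiguity).

The window scan uses 200 m windows advanced in 100 m steps (the
field-standard choice for a zone ~0.75 km wide), half-open on the right so
windows refine a partition. A component needs at least 5 complete
individuals in the window (the data floor is a package choice; none is
inherited), and each reported value is the unweighted mean over loci or
pairs. All estimates are asserted against the allele-frequency bounds on D
at the window's ML frequencies. Gametic (EM-resolved) D is the primary
estimator, matching the ML framing; no composite (Burrows) estimator is
exposed because the ML route covers the use case. No variance or CI is
attached to D.

## Hybrid classification

Two closed-form classifiers for fully diagnostic loci replace MCMC
admixture machinery (whose output labels can instead be read from the
input table):

- a threshold rule on an admixture proportion q (supplied externally or
  proxied by the nuclear hybrid index): hybrids are intermediate q. The
  conventional cutoffs (0.1, 0.9) are the default; a "formula" mode uses
  the midpoint construction lower = (0 + 1/(2L+1))/2,
  upper = (1 + 2L/(2L+1))/2 for L diploid diagnostic loci (1/14 and 13/14
  at L = 3). The two conventions disagree between 1/14 and 1/10; both are
  reproducible by flag because both appear in practice.
- a posterior over the six early-generation genotype-frequency classes
  (two parentals, F1, F2, two backcrosses), multiplying per-locus
  class-conditional genotype probabilities — parental (1,0,0)/(0,0,1),
  F1 (0,1,0), F2 (1/4,1/2,1/4), backcrosses (1/2,1/2,0)/(0,1/2,1/2) —
  across scored loci with a configurable prior. Note that an all-homozygous
  parental genotype does not exclude the same-side backcross (likelihood
  (1/2)^L) or F2 ((1/4)^L): with three loci the posterior for a triple
  EE homozygote is 64/73 parental, 8/73 backcross, 1/73 F2. Simulated
  class draws show parentals and F1s recovered nearly always, while F2 and
  backcross calls are frequently uncertain — the expected behaviour with
  three diploid loci, where those classes overlap heavily.

## Habitat association and the habitat-and-cline model

Class-by-vegetation association is Pearson's chi-square without continuity
correction (expected counts below 5 trigger a warning); elevation
differences use descriptive per-class summaries and the one-way ANOVA
omnibus F (no post-hoc structure). The habitat-and-cline model minimally
nests the shared tanh cline by shifting its center: c + delta 1[MWP] for
the vegetation series, or c + gamma (elev - mean elev), one extra
parameter each, compared by LRT (df = 1); a width-shift variant sits
behind a flag. The covariate must be observed for at least 90% of
individuals. Calibration: under the generator's default conditions (no
genotype-habitat effect beyond the cline) the LRT rejects at 0.056 over
500 null replicates. When the vegetation label is made statistically
independent of position the rate rises to ~0.065 at n = 300 — a
finite-sample anticonservatism of the chi-square reference that decays
with sample size (controls: ~0.055 at n = 300, ~0.045 at n = 1000,
~0.040 at n = 3000) and is worth knowing about when interpreting marginal
p-values near 0.05.

## The synthetic-data generator

`simulate_zone` emulates the study conditions: 335 individuals uniform on
a 3.5 x 1.75 km strip whose long axis has compass heading 207 degrees;
tanh clines per locus with defaults matching the published per-locus
estimates (nuclear widths 0.770/0.799/0.725 km at a common center, mtDNA
width 0.718 km with its center 0.105 km toward the E side); a vegetation
boundary (logistic blur, 0.15 km scale) and an elevation trend
(1420 m + 60 m/km, 60 m noise) confounded with transect position.

Disequilibrium is injected by the tension-zone mechanism: with probability
m(x) = mix_amplitude exp(-|x - mix_center|/mix_scale) an individual is an
unrecombined parental immigrant (all-K with the local consensus-cline
probability, else all-E), which creates heterozygote deficit, inter-locus
D and cytonuclear D jointly, each of magnitude m(x) p(x)(1 - p(x)) at the
haplotype level. Defaults mix_amplitude = 0.7, mix_center = -0.15 km,
mix_scale = 0.5 km put the disequilibrium peak (~0.12-0.15) on the E
flank, as observed in the real zone. The Laplacian kernel is a
convenience; any center-peaked kernel would serve. Individuals whose drawn
nuclear genotype contains alleles of both taxa ("mixed ancestry") carry
the K mitotype with probability mt_asymmetry = 0.9, emulating strongly
asymmetric hybridization; pure-genotype draws follow the mitochondrial
cline itself, which keeps that cline well-defined on the flanks. Because
the override acts on zone-center individuals it *adds* an apparent mtDNA
center shift (~0.1 km) on top of any injected geometric offset; recovery
experiments that target the geometric offset alone therefore disable it
(mt_asymmetry = None).

What the generator does not emulate: spatial clustering along a creek
line, temporal structure across sampling years, genotyping error, linkage
between nuclear markers, and continuous (non-diagnostic) allele-frequency
differences. Passing recovery tests therefore demonstrate correctness of
the estimators under the stated model, not robustness to those
real-data complications.

## Numerical conventions and degenerate inputs

Kilometres are the canonical length unit (the CLI accepts window/step in
metres). 0 ln 0 := 0 throughout. Monomorphic data (no cline, undefined D,
monomorphic focal locus) raise errors rather than returning boundary
estimates; all-missing rows are flagged; empty result sets refuse to
write. Ties in position are pooled before isotonic fitting. Every
randomized routine takes an explicit seed and is bitwise reproducible;
pipeline outputs are pure functions of (input, configuration), and the run
manifest records SHA-256 checksums of every artifact.

## Problem sizes used in validation

The test-suite simulations use the study-scale sizes: n = 300-500
individuals per replicate, 100 replicates for support-limit coverage, 50
for offset recovery and null concordance, and 500 for each LRT
calibration; oracle comparisons use up to 6 observations (isotonic DP
grid) and tables of up to ~30 individuals (disequilibrium grid searches).
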