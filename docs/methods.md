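# Methods

`divsel` tests whether quantitative traits of populations sampled along an
environmental gradient diverge because of selection or because of neutral
demographic history, using only dominant (presence/absence) marker
fingerprints, per-population climate records, and common-garden trait
measurements.  This note describes the statistical machinery, the synthetic
data that stands in for a field study, and the numerical choices made where
the design was open.

## The inference scheme

The pipeline separates three signals that are confounded in raw trait
clines:

1. **Locus-level selection scans** split the marker panel into a small
   "selected" set (candidate targets of divergent selection, or hitchhikers)
   and a large "neutral" remainder.  Three detectors run independently:
   an F_ST-outlier search against a simulated neutral envelope, a
   hierarchical Bayesian F-model with a per-locus selection indicator, and a
   logistic regression scan of band presence on environmental variables.
   Their intersection (configurable) defines the partition.
2. **Distance-matrix regression (GAMOVA / MDMR)** asks, for each trait,
   whether the population trait means predict the pairwise Phi_PT
   differentiation matrix of the selected set and of the neutral set.
3. **Mantel tests** of each Phi_PT matrix against great-circle geographic
   distance detect isolation by distance in either locus set.

The four significance flags map to a divergence scenario per trait:
selected+/neutral− is the selection signature (clinal 1.1 if the selected
set shows IBD, local 1.2 otherwise); selected+/neutral+ means neutral
processes cannot be excluded (2); selected−/neutral+ is neutral geography
(3.1 with IBD, chance 3.2 without); neither is "no_signal".  The classifier
is a total function over the 16 flag combinations.

## Dominant-marker statistics

A dominant marker shows a band for genotypes AA/Aa and none for aa, so
allele frequencies cannot be counted.  With `m` band-absent individuals of
`n` under Hardy–Weinberg, `m ~ Binomial(n, q^2)` in the band-absence allele
frequency `q`.  We estimate `q` by its posterior mean under a Beta prior
(uniform by default; an empirical-Beta option exists), evaluated by adaptive
quadrature to 1e-10 relative tolerance and memoised per `(m, n)`.

Locus F_ST is the weighted among-population variance of the estimated
band-presence frequencies over the total variance.  Two properties of the
posterior-mean estimator matter at common sample sizes (n ≈ 15):

* it carries **sampling variance** (for dominant data roughly
  `p(2-p)/(4n)`, substantially more than the codominant `p(1-p)/(2n)`), and
* its Bayesian shrinkage **attenuates** the spread of the per-population
  estimates.

The default correction (`correction="dominant_exact"`) computes, from the
same binomial tables used for estimation, the exact sampling variance and
the expectation slope of the estimator, both evaluated at the de-shrunk
locus-mean frequency (the observed mean mapped back through the estimator's
expectation curve; this keeps the correction stable where shrinkage is
strong).  The among-population variance is reduced by the mean sampling
variance and rescaled by the mean squared slope.  The denominator uses the
total-variance form `pbar(1-pbar) + s2/K`, so complete fixation yields
exactly 1.  Measured bias at the study-like configuration (12 populations
of 15, background F_ST 0.02) is about −0.003; the simpler `binomial`
correction (+0.005 bias at the same configuration) and `none` remain
available.  A monomorphic locus has no defined F_ST and is excluded from
scans.

Phi_PT — the band-phenotype AMOVA analogue of F_ST — needs no
allele-frequency inference: variance components come from pairwise squared
Euclidean distances between 0/1 band vectors, with significance from
permuting individuals among populations.  Negative estimates are retained.
Individual-level ordination uses classical scaling (PCoA) of Bray–Curtis
distances; negative eigenvalues are reported, not corrected, and percent
variance is relative to the sum of positive eigenvalues.

## The F_ST-outlier envelope

The envelope detector simulates a large number of neutral dominant loci:
ancestral frequency Uniform(0.01, 0.99), population frequencies from the
Balding–Nichols Beta island model at the target background F_ST, dominant
phenotypes sampled at the observed population sizes, and (He, F_ST)
re-estimated **with exactly the estimators used on the data**.  Observed
loci are judged against the simulated loci in their heterozygosity
neighbourhood (sliding window of the nearest 2,000 simulated loci in He);
the empirical p-value is the upper-tail fraction, corrected by
Benjamini–Hochberg, and an outlier must additionally lie above the upper
envelope curve.

The background F_ST is itself a "trimmed mean": loci outside the current
confidence band are excluded and the envelope is rebuilt.  Because trimming
a right-skewed distribution pulls the mean down even under pure neutrality,
the iteration updates the simulation target by the gap between the data's
trimmed mean and the *simulated* loci's own trimmed mean at that target;
at convergence the two agree, which keeps the envelope calibrated (outside
fraction ≈ 5% at a 95% band on fully neutral data) instead of drifting
tight.  Defaults: 1,000,000 simulations, CI 0.95, FDR 0.05, at most 5
trimming rounds.

## The Bayesian F-model

Counts `m_jl ~ Binomial(n_j, (1 - p_jl)^2)`;
`p_jl ~ Beta(theta p_l, theta (1 - p_l))` with
`theta = (1 - F_jl)/F_jl` and `logit(F_jl) = alpha_l * delta_l + beta_j`.
Priors: `alpha ~ N(0, 1.8)`, `beta ~ N(-1, 1.8)`, `p_l ~ Uniform`, prior
odds neutral:selected 10.  Sampling is Metropolis-within-Gibbs with
elementwise logit random walks, proposal scales adapted during pilot runs to
acceptance 0.25–0.45.  The selection indicator is flipped by a
variable-selection move using per-locus Gaussian pseudo-priors for `alpha`
fitted from the pilot runs (which execute with all indicators on) — an
equivalent but simpler alternative to full reversible jump; this is a
deliberate design choice.  The posterior probability of selection is the
posterior mean of `delta_l`, converted to q-values by the running mean of
`1 - PP` down the ranking; loci with q ≤ 0.05 are called.  Default
schedule: 50 pilots of 5,000 iterations, then 250,000 iterations, burn-in
50,000, thinning 20 (10,000 samples).  A non-mixing chain (all acceptance
below 5% after pilots) aborts with a diagnostic.

## The association scan

Each polymorphic locus is regressed on each environmental variable by
univariate logistic regression (individuals inherit their population's
climate values), fitted by batched Newton iteration to 1e-8 with
closed-form 2×2 solves.  Significance needs both the likelihood-ratio G and
the Wald statistic below `alpha / (loci x variables)` (Bonferroni over all
models).  Complete separation is detected as a capped, diverging slope: the
model is flagged non-converged, its Wald test is unusable, and it cannot be
called significant.  The 20 climate variables (plus latitude/longitude) are
also condensed by a standardized PCA whose first three components join the
scanned variables.

The scan treats individuals as exchangeable.  Under population structure
individuals within a population share both their environment and correlated
band frequencies, which inflates both tests (classic pseudo-replication);
even a background F_ST of 0.02 drives the family-wise error of a
Bonferroni-corrected panel scan towards 1.  Its null calibration is
therefore stated — and tested — for bands independent across individuals,
and the pipeline treats the scan as one voice among three intersected
detectors, never as a standalone caller.

## GAMOVA and Mantel

GAMOVA Gower-centres the squared distance matrix, `G = -1/2 J (D∘D) J`, and
reports `pseudo-F = tr(GH)/tr(G(I-H)) * (K-2)` for the hat matrix of
`[1, trait]`.  On a Euclidean distance matrix of a univariate response this
equals the classical regression F exactly (tested to 1e-8).  Phi_PT
matrices need not be Euclidean: G can have negative eigenvalues, the
pseudo-F can be negative, and — the important numerical case — a
near-perfectly explained matrix can drive the residual trace *negative*,
flipping the sign of an excellent fit.  The permutation test therefore
ranks permutations by the model sum of squares `tr(GH)`, which orders
identically to F whenever the residual trace is positive (tr(G) is
permutation-invariant) and stays monotone in fit quality otherwise.  The
pseudo-F itself is reported as defined, negatives included.  Each trait is
tested in its own single-predictor GAMOVA; trait values are permuted across
populations, 9,999 permutations by default, no multiplicity correction
across traits.

The Mantel statistic is the Pearson correlation of strict lower triangles
with simultaneous row/column permutation of one matrix; the default
alternative is one-sided positive (the isolation-by-distance question), and
an exhaustive mode enumerates all relabelings for small K.  Geographic
distances are great-circle (haversine, Earth radius 6,371 km).

## Synthetic data

The generator emulates a ~250 km aridity transect: 12 populations of 15
individuals, 20 bioclimatic variables that are affine in transect position
with correlated noise (annual precipitation spanning 200 mm at the mesic
end to 100 mm at the arid end), 700 neutral loci at background F_ST 0.02,
and 30 clinal loci whose logit band-allele frequency adds `slope * z` (z =
standardized environmental value) on top of the same neutral island-model
draw — so zero slope reduces exactly to neutrality, and the default slope
1.5 gives realized F_ST ≈ 0.25.  Dominant phenotypes follow
`P(band) = 1 - (1-p)^2` (Hardy–Weinberg, F_IS = 0 — an assumption surfaced
in configuration, as no within-population inbreeding estimate is available).
24 replicate individuals are appended with a 9% per-locus bit-flip rate to
emulate scoring error.

Spatial autocorrelation of the neutral deviates (the IBD knob) runs through
a Gaussian copula with an exponential kernel, correlation length one third
of the transect, and amplitude `ibd_strength` (off-diagonal correlation
scaled by its square, default 0.2).  Two calibrations keep the knob honest:
the marginal Beta variance is inflated by `1/((K/(K-1))(1 - mean C))` so the
realized within-locus differentiation stays at the nominal background, and
the amplitude default is deliberately mild — at full amplitude every smooth
clinal trait correlates with the *neutral* differentiation matrix, which
collapses all selection scenarios into the confounded class and would make
the design's central contrast untestable.  The cost is that the neutral
background's own Mantel test is only sometimes significant at the default;
raise `ibd_strength` to study strongly autocorrelated backgrounds.  A
related consequence: because the simulated selection is clinal along the
same transect, a trait coupled purely to geography is also attributed to
the selected set (scenario 1.1 rather than 3.1) whenever the neutral
background carries little spatial signal — the design can only separate
clinal selection from clinal neutrality through the neutral matrix's own
geography, which is exactly what a weak isolation-by-distance background
withholds.

Traits come in three generative flavors: "selected" (standardized
population mean of the clinal-locus frequencies plus individual noise),
"neutral_ibd" (transect position plus noise) and "random" (noise); defaults
couple trait V01 to selection, V02/V07 to geography, the rest to noise,
with coupling 1.0 and noise SD 1.0.  Leaf outlines are ellipses
(population-specific aspect ratio, coupled to the selected trait across
1.5–3.5 in the full bundle) with a 9-lobe sinusoidal radius modulation
(amplitude < 0.5 keeps them star-shaped, hence never self-intersecting);
flowers are 37-point configurations (center, 4 petal tips, 32 margin
semilandmarks at 25/50/75/95% of petal length) with isotropic landmark
noise.

What the generator does **not** emulate: linkage between loci, admixture or
hierarchical population structure, non-equilibrium demography, genotype ×
environment interaction in traits, missing-data patterns of failed lanes,
or the image-segmentation noise of real scanned leaves.  Passing tests
demonstrate statistical correctness of the machinery under the island-model
world, not robustness to those complications.

## Morphometrics

Leaf outlines are resampled to equal arc length and decomposed into
Kuhl–Giardina elliptic Fourier coefficients (chain integrals over the
closed polygon), normalized by the first-harmonic ellipse: starting point to
its semi-major axis, frame rotated to that axis, size divided by its
length — after which `a1 = 1` and the first-harmonic orientation is 0 to
1e-9.  The parameterization is the chain length by default; a uniform
(per-vertex) option exists, under which an ellipse sampled at equal angles
is exactly its first harmonic.  Harmonic power is
`(a² + b² + c² + d²)/2`; fifteen harmonics capture ≥ 99% of the power of
deeply lobed synthetic leaves, which is the adequacy figure
`scripts/acceptance.py` recomputes.  Leaf shape scores (V15–V17) are a
centered PCA of the normalized coefficients; flower scores (V11–V14) come
from GLS Procrustes superimposition (translate, scale to unit centroid
size, iterate rotations to the consensus to 1e-10; semilandmarks are not
slid, preserving the plain-GLS semantics of the scores) followed by
centered PCA of the aligned coordinates.  The final Procrustes frame is
rotated onto the consensus' principal axes with a fixed sign convention, so
results are independent of input order; PCA signs are fixed by making each
axis' largest-magnitude loading positive.  Scalar measures are the shoelace
polygon area (× scale², cm²) and the mean center-to-tip petal length
(× scale, mm).

One landmark-count note: descriptions of this flower scheme sometimes give
5 landmarks + 34 semilandmarks (39 points); the arithmetic used here is
1 center + 4 tips + 4 petals × 8 margin points = 37, matching the
configuration the PCA consumes.

## Numerical and design choices

* Delimited I/O is tab-separated UTF-8, '.' decimal, "NA" missing; marker
  tables round-trip exactly, result tables are written at fixed precision
  with a JSON run manifest (config, seed, version).
* Missing band scores: default drops the affected individual;
  `as_absence` scores them 0.  The choice is configuration, not silent.
* Same seed + same configuration reproduces every output byte-for-byte;
  all stochastic stages draw from seeded generators.
* The scenario significance level is 0.05 per test with no correction
  across the 17 traits; the Mantel matrix defaults to Phi_PT (an F_ST-based
  matrix is a configuration switch).
* Test-suite problem sizes: detector calibration uses 20 neutral replicates
  of 700 loci with 50,000-simulation envelopes; power uses one 730-locus
  dataset with the reduced MCMC schedule 20,000/5,000/10 after 10 pilots of
  500; scenario recovery uses 10 replicates with 20,000-simulation
  envelopes and 999 permutations; the association-scan null uses 200
  replicates of 500 × 5 models.  These sizes were chosen as the smallest
  that hold the Monte-Carlo error of each criterion comfortably below its
  acceptance band.

## Known limitations

* All allele-frequency machinery assumes Hardy–Weinberg within populations;
  inbreeding biases both the Zhivotovsky estimates and the F-model.
* The logistic scan's tests are anticonservative under population structure
  (see above); its Bonferroni control is guaranteed only for exchangeable
  individuals.
* The F-model's pseudo-prior indicator move mixes slowly for borderline
  loci; posterior probabilities near the decision boundary need the full
  schedule, not the reduced one, for two-decimal stability.
* GAMOVA power drops quickly below ~8 populations; with 4–7 populations
  only very strong trait–matrix correlations reach p ≤ 0.05 at any
  permutation count.
* The scenario classifier inherits every miscalibration of its four input
  tests; it adds no error control of its own.
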