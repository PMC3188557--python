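# Methods

This note documents the statistical model behind `wingfa`, the choices made
where the design was genuinely open, the synthetic-data generator that the
test suite measures everything against, and the known limitations.

## The sides model

All FA estimation assumes the classical sides model. For individual *i*,
side *s* ∈ {L, R} (coded d<sub>L</sub> = −½, d<sub>R</sub> = +½) and
digitization replicate *r*:

    y_isr = m + a·d_s + b_i + f_is + e_isr

with individual effects b<sub>i</sub> ~ N(0, σ²<sub>I</sub>), side-specific
FA deviations f<sub>is</sub> ~ N(0, σ²<sub>F</sub>) independent across
sides, and digitization noise e<sub>isr</sub> ~ N(0, σ²<sub>ME</sub>). The
constant *a* is directional asymmetry. Under this model, for the balanced
two-way ANOVA:

    E[MS_individual×side] = M·σ²_F + σ²_ME        E[MS_error] = σ²_ME

so **FA10** = (MS<sub>int</sub> − MS<sub>err</sub>)/M is an unbiased
estimate of the per-side FA variance σ²<sub>F</sub>, corrected for both ME
and DA (DA moves only the Side stratum — an exact algebraic identity that
the tests assert at 1e−9). **FA4** = var(R−L) estimates
2σ²<sub>F</sub> + 2σ²<sub>ME</sub>/M; it is reported as the plain variance
of the right-minus-left differences, not the 0.798·√var folded-normal
variant, with replicates averaged per side first when M ≥ 2.

F-tests use the mixed-model denominators (Side and Individual over the
interaction; the interaction over Error). FA comparisons between genotypes
are two-sided variance-ratio F-tests — FA4: the ratio of the difference
variances with (n₁−1, n₂−1) df; FA10: the ratio of the interaction mean
squares with their interaction df, with two-sided p = 2·min(tail, 1−tail).
Negative FA10 estimates (ME exceeding the interaction MS) are returned
flagged, never silently truncated, and excluded from ratio comparisons with
a warning: truncation at zero would bias fold-changes upward.

Families of comparisons are adjusted with the Holm step-down procedure
(sort ascending, multiply the i-th smallest by m−i, enforce monotonicity,
cap at 1).

## Shape: superimposition and the Procrustes ANOVA

Generalized Procrustes analysis scales every configuration to unit centroid
size, reflects the designated side (left by default, configurable) about
the vertical axis so both sides share one shape space, and iterates
least-squares rotation to an updating consensus. Numerical choices:

- convergence tolerance 1e−10 on the consensus change, at most 1000
  iterations. Biological datasets converge in a handful of iterations;
  uniformly random configurations contract slowly (ratio ≈ 0.97 per
  iteration) and need several hundred, which costs milliseconds since the
  2D rotations have a closed form and are batched. The consensus
  orientation is pinned to the previous iterate each step to remove the
  free rotational drift mode.
- after convergence, a final alignment pass against the converged consensus
  and an orthogonal projection onto the tangent space (each aligned
  configuration satisfies ⟨x, μ⟩ = 1 exactly). Centering, the projection,
  and the rotation optimality condition make translation, scale and
  rotation dimensions exactly zero, so PCA of the aligned coordinates has
  exactly 2k − 4 = 26 non-zero eigenvalues for the 15-landmark wing
  (numerical-zero threshold: max eigenvalue × 1e−10).
- PC loadings are oriented so each one's largest-magnitude coefficient is
  positive, making outputs platform-reproducible; all angle statistics use
  the absolute cosine, so the sign convention never affects inference.

The Procrustes ANOVA pools the sides-model sums of squares over all 2k
aligned coordinates and multiplies each conventional df by the shape
dimension 2k − 4; it is numerically identical to summing 2k per-coordinate
univariate ANOVAs (asserted to 1e−9 relative).

**One superimposition, not one per group.** All group-wise shape statistics
(per-genotype ANOVAs, FA matrices) are computed on subsets of a single
common GPA. Separate per-group superimpositions would leave each group's
tangent space in an arbitrary rotation of its own, making cross-group PC1
angles meaningless; this is the standard matching-symmetry practice. A
`frame_rotation` helper maps results into the frame of an external template
(used by the recovery tests to compare against the generator's truth).

Allometry correction is a multivariate regression of the PC scores on log
centroid size, residuals exactly uncorrelated with size; the pipeline
exposes both raw and corrected paths because discriminant analyses can
reasonably be run on either. CVA solves the generalized eigenproblem of
among- versus pooled within-group covariance on the PC scores, normalizes
canonical scores to unit pooled within-group variance, and reports the
shape change per axis as the regression of the shape variables on the
canonical scores. The pipeline feeds CVA and the MANOVA at most
n − g − 1 leading PCs so the within-group covariance stays invertible at
small n.

## FA pattern matrices and the angle tests

The FA pattern of a group is the matrix analogue of FA10. With
replicate-averaged side differences d<sub>i</sub> (R − L, in score space)
and per-individual error cross-products E<sub>i</sub>:

    FA = Cov(d_i)/2 − (Σ_i E_i / (2n(M−1))) / M

Its trace equals the shape dimension times the Procrustes-ANOVA FA10
(exact identity, tested at 1e−9). ME correction can make the matrix
indefinite; negative eigenvalues are reported, and clipped to zero only for
variance shares and visualization. With M = 1 the raw DA-centered
difference covariance (halved) is returned and flagged as uncorrected.

Similarity of two groups' dominant FA directions is the angle between their
FA-matrix PC1s, in [0°, 90°] via the absolute cosine. Two nulls:

- **Random-vector null**: angles between pairs of isotropic random vectors
  of the same dimension; p = (# null angles ≤ observed)/n_draws, so small p
  means "more similar than chance". In high dimension random vectors are
  nearly orthogonal (the d = 26 null mean is ≈ 80.8°), which is why even
  a 40° angle can be highly significant. A published variant of this
  p-value formula mixes a count into a probability; the conventional count
  form is the default and the literal variant sits behind a
  `literal_formula` flag for comparison.
- **Bootstrap null**: individuals are resampled with replacement within a
  genotype and the FA matrix + PC1 recomputed per resample; each iteration
  records the angle between two *independent* resamples, so the null
  distribution is "identical direction + sampling error on both sides".
  p = (# null angles ≥ observed)/n_boot; a large p means the two directions
  are as close as identical ones would appear. For a pair of genotypes the
  null samples of both groups are pooled, which uses all the information
  and keeps the test symmetric in the pair. A one-resample-vs-original
  variant is available by flag. Resamples are recomputed in the fixed
  tangent space of the original superimposition: re-running GPA per
  resample would change results far below sampling error at these sample
  sizes while multiplying cost by the bootstrap count.

Both nulls require an explicit seed; defaults are 10,000 draws. Degenerate
resamples (non-positive leading eigenvalue) are skipped and counted, with a
warning above 1%.

## Antisymmetry and allometry screens

Right-minus-left distributions are screened before interpreting FA:

- excess kurtosis (platykurtosis signals antisymmetry),
- a dip-style unimodality statistic: the ECDF of a unimodal sample is
  convex left of the mode and concave right of it; the statistic is the
  minimum over candidate modes of the larger convex/concave-envelope
  violation, located by bisection (the left violation grows with the mode
  index, the right one shrinks). Its null distribution is
  distribution-free, so the p-value is calibrated by Monte Carlo against
  uniform samples of the same n (cached per n; 200 draws by default),
- a Shapiro–Wilk normality p for reference.

"Antisymmetry suspected" requires both excess kurtosis < −0.5 and
unimodality rejected at α = 0.05. These numeric thresholds are this
package's operationalization of what is often done by eye; on N(0,1)
samples of n = 500 the false-flag rate is ≤ 5%, and a ±3 mixture with
component sd 0.3 is flagged ≥ 95% of the time (both tested). The FA
allometry screen regresses |R − L| on individual size within each group
(≥ 10 individuals required) and across group means (≥ 3 groups).

## Cell counting and compensation statistics

Images are thresholded (fixed cutoff or Otsu) and hairs counted as
8-connected components — 8-connectivity keeps thin diagonal hair marks
single. Objects touching the window border are counted (discarding them
would bias density low; switchable). Three 256×256 windows, shifted by one
window width along the image x-axis (the proximo-distal stand-in; offsets
configurable), are averaged; a Poisson dispersion χ² across the three
counts flags density inhomogeneity. Cell size is 1/mean-count in arbitrary
units; the 0.07 mm² calibration is metadata only. Whole-image totals can
exclude a vein/margin mask, reproducing the deliberate, genotype-stable
undercount of vein cells.

Compensation statistics per genotype: Pearson r of cell size vs cell
number (pairwise Fisher r-to-z comparisons), and the residual variance of
the size-on-number regression (df n−2), compared across genotypes by a
Levene test and pairwise two-sided F tests with Holm adjustment. When every
group fits exactly (residual variances at rounding level), the Levene test
is reported as degenerate rather than computed on noise. Cellular FA is
FA4 of cell size and cell number; per-individual |R − L| asymmetries are
correlated (Pearson and Spearman) with the unsigned wing-size asymmetry.

## The synthetic-data generator

`wingfa.simulate` draws data *under the sides model itself*, with nuisance
transforms applied afterwards so the estimation chain is genuinely
exercised: latent shape = template + DA·d_s·u_DA + individual deviation +
per-side FA deviation; then group-specific scale, random rotation (uniform
on [0, 2π)), random translation, mirroring of the left side, and
per-replicate digitization noise. FA covariance is isotropic
(σ²<sub>F</sub>·I) or rank-1 dominated (λ·uuᵀ plus an isotropic floor);
`random_shape_direction` draws directions orthogonal to the similarity
subspace so they survive superimposition. The 15-point template is a
wing-like landmark layout (margin and vein intersections) at unit scale.

Default study conditions: 4–6 genotype×sex cells of 40 individuals, M = 2
digitization replicates, σ²<sub>ME</sub> = 1e−6 per coordinate (small
against FA, as replicated digitization of wings typically shows), control
shape-FA σ²<sub>F</sub> = 1e−5 per coordinate against individual variance
1e−4, log-size FA variance 1e−5 with a 37-fold inflation in the
gain-of-function genotype and 10-fold in the loss-of-function one, and
shape-FA inflations of 8× and 4× — the order of magnitude of the genetic
perturbations this pipeline is designed to detect. Hair-dot images place
non-overlapping disks (rejection sampling; guaranteed 8-disconnected) so
the true count is exact by construction.

What the generator does *not* emulate — and hence what green tests do not
establish about real data: non-Gaussian FA, landmark-specific digitization
error, within-dataset magnification differences, real microscopy artifacts
(uneven illumination, debris, overlapping trichomes on veins), or
developmental covariance between size and shape beyond linear allometry.

## Test and simulation sizes

Monte-Carlo checks use the sizes at which their tolerances were derived:
variance-component recovery at n = 300, M = 2 over 500 replicates (5%
tolerance); fold-ratio sampling at n = 50/genotype over 500 replicates;
type-I calibrations over 1,000–2,000 replicates (±1.5 points); direction
recovery and the two angle nulls over 100 simulations of two 200-individual
genotypes with 200 bootstrap draws each. One caveat is worth stating
plainly: a variance ratio estimated from 50 individuals per group has the
spread of 37·F(49, 49), which places ~17% of estimates outside [25, 55] —
no estimator of this design can keep 90% of draws inside that band; the
corresponding check documents this sampling-theory fact rather than a
defect of the implementation (doubling n per group brings the coverage to
~95%).

## Known limitations

- Balanced designs only: unbalanced side/replicate structures are rejected
  with a validation report rather than fitted (no REML / Satterthwaite
  machinery); incomplete individuals must be excluded by the caller.
- FA10 assumes the sides model's independence structure; individual-level
  variation in DA would inflate it (a caveat inherent to the index, not
  testable without replicated genotypes).
- The bootstrap angle null, like all bootstraps of eigenvectors, is
  slightly anticonservative when the leading eigenvalue gap is small; the
  uniformity of its p-values is verified only under a dominant rank-1
  direction.
- 2D landmarks only; no semilandmarks, no thin-plate-spline visualization
  (PC1 displacement fields are drawn as vectors at landmarks instead).
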