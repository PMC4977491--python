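# Methods

`craniomorph` implements a landmark-based geometric-morphometric biodistance
analysis for bilaterally symmetric skeletal structures (crania, mandibles),
together with a synthetic data generator that makes every stage testable
against known ground truth. This note documents the models, the numerical
choices, and what the synthetic data do and do not establish.

## Data model

A specimen is a k×3 matrix of homologous 3D landmark coordinates in mm
(k = 39 for crania, 33 for mandibles in the default configuration; arbitrary
k in generic mode) with a per-landmark missingness mask and metadata
(cultural horizon, dietary group, sex, anatomical unit). Bilateral object
symmetry is described by a `SymmetryScheme` partitioning the landmarks into
left/right pairs and midline points; the anatomical identity of each index
is configuration (YAML), not code. Specimens with ≥ 20% missing landmarks
are excluded (the threshold is strict "<", so 7/39 = 17.9% is kept while
7/33 = 21.2% is not).

## Missing-landmark estimation

Estimation runs in two passes, mirror-imaging first, thin-plate spline
second; neither pass can increase the number of missing landmarks.

**Mirror-imaging.** A missing bilateral landmark whose partner is present is
replaced by the partner's reflection across the specimen's midsagittal
plane. The plane is estimated jointly from all symmetry information: it
minimizes squared distances of present midline landmarks and complete-pair
midpoints to the plane while aligning its normal with the left–right
difference vectors, via the eigenproblem min‖n‖=1 nᵀ(C − B)n, where C is the
centered scatter of the midline/midpoint set and B the sum of pair-difference
outer products. The difference term is what makes the fit well-posed in the
stated minimal case of two complete pairs and no midline landmarks; for
exactly symmetric configurations every term vanishes and the plane is exact.
At least 3 midline landmarks or 2 complete pairs are required; otherwise the
landmark falls through to the TPS pass.

**Thin-plate spline.** Remaining missing landmarks (midline, or pairs missing
on both sides) are mapped from a complete reference configuration through the
3D TPS fitted on the shared present landmarks — the interpolant that
minimizes bending energy. We use the standard 3D kernel U(r) = −r, which is
conditionally positive definite under the affine side conditions, so the
bending energy trace(WᵀKW) is nonnegative and zero exactly for affine maps;
affine deformations are therefore reproduced exactly. The reference is the
Procrustes mean of fully complete specimens of the same group when a group
has ≥ 3 of them, otherwise the global complete-specimen mean, restored to
mm scale. A single estimation pass is used (no EM iteration), and imputed
landmarks enter all downstream statistics; each specimen carries provenance
recording which landmarks were imputed and by which method.

**Observer error.** `intra_observer_error` summarizes repeated digitizations
as the per-landmark mean Euclidean deviation from the specimen-wise replicate
centroid, averaged over specimens. For isotropic digitization noise σ per
coordinate and r replicates the grand mean has the closed form
σ·√(1 − 1/r)·2√(2/π) (a scaled χ₃ mean), which the tests use as the oracle;
the conventional benchmark of 0.8 mm grand-mean precision corresponds to
σ ≈ 0.55 mm at r = 6.

## Superimposition and the symmetric component

Generalized Procrustes analysis translates configurations to a common
centroid, scales them to unit centroid size (full Procrustes fit — the unit
size is retained throughout), and iteratively rotates each onto the
unit-size mean until the decrease of the total Procrustes sum of squares
falls below 1e-10. For centered unit-size shapes the renormalized arithmetic
mean is the optimal unit-size mean, so the total SS is provably
non-increasing across iterations. Reflections are disallowed in all
superimpositions (det = +1 enforced by an SVD sign flip on the smallest
singular axis) so biological handedness is preserved; ties at a zero
singular value are broken deterministically the same way.

A Procrustes solution is only defined up to one global rotation. To make
results reproducible and invariant to arbitrary rigid motion and scaling of
the inputs, the converged mean is put into a canonical principal-axes frame
(axes ordered by inertia, each axis signed so its largest-magnitude landmark
coordinate is positive, proper rotation enforced) and all aligned shapes are
rotated with it. Input-order independence follows from the same
canonicalization.

Tangent-space projection is the orthogonal projection of each vectorized
aligned shape onto the hyperplane orthogonal to the mean-shape direction;
it is idempotent and agrees with Procrustes distances to first order for
the small shape variation typical of within-species cranial data.

The symmetric component of each shape is the average of the aligned
configuration and its mirror image, relabelled under the pairing scheme and
re-superimposed by ordinary Procrustes rotation. Because the optimal
re-superimposition rotation R satisfies JRJ = Rᵀ, this average is an exact
fixed point of the reflect–relabel–align map: the output is exactly
symmetric and the operation idempotent (both at ~1e-10 numerically, asserted
in tests). A final GPA over the symmetric shapes yields the coordinates all
downstream statistics use; whether one should instead average within the
original alignment is not standardized, and the re-run is our declared
choice. Original centroid sizes (mm) are carried through. Crania and
mandibles are always processed as separate datasets.

## Ordination and allometry

Total-variance PCA eigen-decomposes the sample covariance (divisor n − 1) of
the tangent coordinates via SVD. Downstream analyses use the smallest
leading set of PCs whose cumulative variance fraction reaches 95%.

Between-group PCA eigen-decomposes the covariance of the group mean vectors,
weighted by group size n_g with divisor n − 1 — with that convention bgPCA
coincides exactly with total PCA when every specimen is its own group — and
projects *all* specimens onto those axes. With g groups at most g − 1
eigenvalues are nonzero. Variance fractions are reported both relative to
the between-group variance and relative to total variance, since either
denominator is defensible for the "variance explained by bgPC1" of a
scatter plot. bgPCA's known tendency to overstate group separation is not
corrected (no cross-validation); consumers should read supports and MANOVA
p-values, not bgPCA scatter, for inference. Eigenvector signs are fixed by
making each vector's largest-magnitude entry positive.

Shape change along an axis is visualized by `shape_at_score`, the mean
vector plus score × eigenvector folded back to k×3.

Allometry is tested by OLS of each retained PC score on centroid size (raw
CS by default; log-CS via an option — the choice matters little over the
±10% size ranges typical here), with per-axis slope, R² and two-sided p,
plus a multivariate summary R²: trace of the predicted-score covariance over
trace of the total score covariance.

## Group statistics

Size differences: one-way ANOVA of centroid size on group, with all-pairs
Tukey HSD (Tukey–Kramer under unbalanced group sizes, via statsmodels).

Shape differences: MANOVA on the retained PC scores using Wilks' Λ =
det(W)/det(T) with Rao's F approximation (exact whenever the score dimension
or the hypothesis degrees of freedom are ≤ 2; Pillai's trace is also
reported). The effect size R² is trace(B)/trace(T) over the between-group
and total sums-of-squares matrices of the scores; 1 − Λ is reported
alongside, since "coefficient of determination" has no unique multivariate
definition. In the balanced univariate case the two coincide exactly. When
n − g ≤ q the trailing score columns are dropped with a warning. The
pipeline runs a fixed battery of groupings: cultural horizons (all samples;
without the hunter-gatherer horizon) and dietary groups (HG/EF/F; HG versus
all farmers combined; EF versus F only), with sexes pooled throughout.

Biodistance: Mahalanobis distances between group mean score vectors,
D_ij = √((m̄_i − m̄_j)ᵀ W⁻¹ (m̄_i − m̄_j)), with W the pooled within-group
covariance (unbiased divisor n − g), computed through a Cholesky solve.
Distances are reported unsquared. Note that with q retained PCs the plug-in
estimate is inflated by roughly a factor √((n−g)/(n−g−q−1)); at study-like
sizes (n ≈ 69, q ≈ 38) this is substantial, which is why consistency is
asserted at n = 200/group and why estimated distances on study-sized
synthetic data exceed their generating values.

## Neighbor-Joining trees and bootstrap

The Saitou–Nei agglomeration with the Q-criterion is applied to the group
distance matrix; ties in Q are broken by the lexicographically smallest
active-node pair, making the tree deterministic. On additive matrices the
tree metric reproduces the input exactly (verified up to 8 taxa at 1e-9).
Negative branch lengths on non-additive inputs are reported as-is with a
flag; a clamp-to-zero copy exists for display. Trees are exported as Newick
with bootstrap percentages as internal-node labels.

Cluster reliability uses stratified specimen bootstrap: specimens are
redrawn with replacement within each group (preserving group sizes), and
total PCA → 95% retention → Mahalanobis → NJ is rerun per replicate; the
support of an internal edge is the percentage of replicate trees containing
the same leaf bipartition. The Procrustes alignment is treated as fixed
preprocessing (a config flag can re-run the full GPA per replicate; the
fixed-alignment default is standard practice and orders of magnitude
cheaper). Replicates with singular within-covariance are skipped and
counted, with a warning above 5%.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes:

- an exactly symmetric template (jittered half-ellipsoid, mirrored; midline
  on the y = 0 plane), centered, centroid size 150 mm — a realistic cranial
  scale for the centroid-size convention used here;
- per-group mean-shape displacements that are exactly symmetric and
  orthogonal to the template's similarity orbit (translations, rotations,
  scaling), so they survive Procrustes alignment unchanged to first order;
- symmetric landmark noise drawn as P_sym·w with w isotropic
  (sd `shape_noise_sd` per coordinate, default 2.0 mm at the 150 mm template
  scale — a typical within-group craniometric landmark dispersion, of which
  digitization error at the 0.8 mm benchmark is a minor part);
- fluctuating asymmetry as (I − P_sym)·v (default 0.5 mm equivalent), which
  symmetrization removes;
- lognormal centroid sizes (default CV 2.5%), with the hunter-gatherer group
  shifted +3 within-group SD of log size in the study-shaped design;
- a random rigid motion and scale per specimen, and MCAR missingness capped
  below 20% per specimen by rejection (MCAR is the weakest assumption; no
  mechanism is modeled).

Because the noise covariance restricted to the symmetric tangent subspace is
exactly isotropic under this construction, the generating Mahalanobis
distance between groups g and h has the closed form |δ_g − δ_h| /
`shape_noise_sd`, which consistency tests compare pipeline estimates
against. The study-shaped design (`table1_design`) uses the study's group
sizes (69 crania 8/10/28/13/10; 97 mandibles 18/21/27/23/8), a strongly
displaced hunter-gatherer group (default 8 within-group SD in shape) and
mild farmer differentiation (default 2 SD).

What passing on synthetic data does *not* show: real cranial variation has
anatomically structured, strongly anisotropic covariance concentrated on few
directions, group sizes this small make Mahalanobis estimates substantially
inflated, and real missingness is not MCAR. In particular the isotropic
noise spreads total variance over all tangent dimensions, so bgPC1's share
of *total* variance on synthetic data (~10–20%) is far below what
low-rank biological covariance produces on real data; the generator
validates machinery, not biology.

## Problem sizes and numerical defaults

Convergence tolerance for GPA is 1e-10 on the SS decrease (max 200
iterations); TPS systems are solved densely (k ≤ 39 keeps them tiny);
distance-matrix symmetry is validated at 1e-8. Simulation-based checks use
sizes chosen to keep the full suite fast while leaving clear margins:
50 datasets of n = 30, k = 39 for GPA invariants; n = 200/group for
Mahalanobis consistency (15% tolerance); 1000 replicates for null
calibration of ANOVA/MANOVA (acceptance band 0.035–0.065 at α = 0.05) and
for bootstrap supports.

## Known limitations

- Single imputation only; imputation uncertainty is not propagated.
- bgPCA overstatement of separation is reported, not corrected.
- The bootstrap resamples scores under a fixed alignment by default.
- No sliding semilandmarks, no directional/fluctuating asymmetry analysis as
  an end product, no mesh/scan I/O.
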