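# Methods

## Measurement model

Each specimen is an ordered set of 18 named skeletal landmarks in
millimetres.  Eight Euclidean distances are defined on fixed landmark
pairs — V1 (nasion–pogonion), V2 (nasion–spina nasalis anterior),
V3 (spina–pogonion), V4 (fronto-orbital suture r – inferior orbital
edge r), H1 (fronto-orbital suture r–l), H2 (condyle r–l), H3 (upper
first molar bone level r–l), Z1 (inferior orbital edge r – condyle r) —
and eight proportions are formed from them:

P01 = V1/H1, P02 = V1/H3, P03 = V1/H2, P04 = V1/V3, P05 = V1/V4,
P06 = V1/Z1, P07 = V3/H1, P08 = H1/H3.

Two definitions required a decision.  The source abbreviation table for
this proportion scheme writes P05 as "V1/V6", but no V6 distance is
defined anywhere in the scheme; V4 is the only vertical distance not used
by any other proportion and the only one producing ratios of the reported
magnitude (≈ 5), so P05 defaults to V1/V4 and the substitution is flagged
in report metadata.  P07 is printed with a dash ("V3–H1"); a literal
difference is not scale-invariant and contradicts the dimensionless use of
the proportions, so P07 defaults to the ratio V3/H1.  Both are
configurable through the proportion-definition table, and proportions are
always computed on raw millimetre coordinates (all defaults are ratios, so
this is equivalent to computing them after superimposition, but it keeps
the literal-difference alternative well-defined).  V2 is measured and
reported but enters no default proportion.  Note that the reported
normative P04 means (≈ 0.92–1.02) imply V3 ≈ V1, which makes a literal
V3/H1 evaluate near P01 (≈ 1.1) rather than near the reported P07 values
(≈ 1.8); the default keeps the literal formulas and reports what they
measure.

Validation is strict: exactly 18 uniquely named landmarks, finite
coordinates, no exactly coincident pair; failures name the offending
landmark.  Invalid specimens are dropped from the pipeline with a logged
reason, never imputed.

## Procrustes superimposition

Pairwise alignment is the classical least-squares similarity fit: both
configurations are centred, the rotation comes from the SVD of the
cross-covariance matrix with the smallest singular vector's sign flipped
whenever the determinant would be negative — improper rotations
(reflections) are never returned — and the optimal scale is the ratio of
the corrected singular-value sum to the source's squared norm.

Generalized Procrustes analysis normalizes every shape to unit centroid
size (root summed squared deviation from the centroid), takes the first
shape in input order as the initial reference, and iterates
rotation-alignment of all shapes to the running mean, re-averaging and
renormalizing the mean to unit size, until the mean moves by less than a
tolerance in Procrustes distance (default 1e-8, max 100 iterations; both
configurable).  Full per-iteration scale optimisation is available behind
`scale_per_iteration` for users who prefer the alternative convention; the
default (pre-normalization only) is simpler and the invariance tests show
the result is insensitive to input order and pose at well below test
tolerances.  Tangent-space projection of the aligned shapes is not
performed; it is a possible extension point.

The Procrustes distance used for convergence and testing is the symmetric
full-Procrustes RMS misfit: with both configurations at unit centroid
size it reduces to sqrt((1 − (Σσ)²)/k), where Σσ is the corrected
singular-value sum, which is symmetric in its arguments by construction.

## Statistics

Group comparison is per proportion: Welch's unequal-variance *t*-test
(two-sided) by default, matching common statistical practice in R-based
studies; pooled-variance Student's *t* is available via `equal_var`.  The
eight p-values of one comparison table are adjusted together by
Benjamini–Hochberg step-up; correction is never pooled across tables
(each sex comparison and each within-sex cluster comparison is its own
family of eight).  Significance is adjusted p < α, default α = 0.05.
Adjusted p-values are rounded (3 decimals) only in the text report; full
precision is retained in the CSV/DataFrame outputs.

The normality screen is a one-sample Kolmogorov–Smirnov test against a
normal with the sample's own mean and standard deviation, p from the
asymptotic KS distribution.  Estimating the parameters from the same
sample makes this screen anticonservative (the Lilliefors effect); the
screen is implemented as stated because that is the procedure this class
of study reports, and a Lilliefors-corrected variant is exposed via a
flag.  In the pipeline, degenerate cells (constant samples) record NaN
with `normal_assumed = False`, and a comparison between two identical
constant samples is recorded as "no evidence of difference" (t = 0,
p = 1) rather than aborting the run; the low-level `ks_normality` and
`welch_t` functions still raise on these inputs.

## Sub-phenotype clustering

k-means runs on the eight proportions, z-scored by default: the
proportions differ about five-fold in scale (P05 ≈ 5 vs P04 ≈ 1), so
unscaled clustering would be dominated by P05.  Unscaled mode exists to
probe that sensitivity, and the report records which was used.  The
algorithm is Lloyd with k-means++ initialisation, best of 20 restarts,
deterministic given the seed (Hartigan–Wong, the common R default, differs
immaterially at the separations involved here).  Degenerate inputs (fewer
distinct feature vectors than k) warn and collapse to a single effective
centroid.

The elbow curve reports total within-cluster sum of squares for
k = 1..k_max, with an automated suggestion at the maximum discrete second
difference of the curve — a proxy for the visual elbow.  The cluster count
used by the pipeline is always an explicit configuration input (default
k = 2); the elbow is a logged diagnostic only.

With k = 2, the cluster with larger mean P01 is labelled dolichofacial,
the other brachyfacial; exact P01 ties break on mean P02.  Any other k
leaves clusters unlabelled with a warning.

## Thin-plate-spline morphing

The 3D TPS uses the biharmonic kernel U(r) = −r (the 3D analogue of the
2D r²·log r kernel); the +r sign convention is available and yields the
identical map with negated weights.  The bordered system
[[K + λI, P], [Pᵀ, 0]] is solved directly (n = 18 control points), giving
kernel weights that satisfy the orthogonality side conditions and, at
λ = 0, exact interpolation of the targets.  λ defaults to 0 (pure
interpolation); small positive values are exposed for noisy landmark
placements and monotonically reduce the bending-energy quadratic form.

A GPA mean shape has unit centroid size, so morphing a millimetre-scale
mesh toward it directly would collapse the mesh.  `morph_template`
therefore first similarity-aligns the target mean onto the template's own
landmark configuration (rotation + translation + scale), then solves the
TPS from the template landmarks to those aligned targets and transports
every mesh vertex.  The morph changes only shape, never gross size or
pose; mesh topology (face list, vertex count) is preserved exactly, and
landmarks may be free 3D points near the surface — they are never snapped
to vertices.

## Synthetic cohorts

The simulator inverts the measurement model.  Fixing H1 = `base_scale_mm`
(default 100 mm, a realistic fronto-orbital width) and the targets for
P01–P06 determines V1, H3, H2, V3, V4 and Z1; a bilaterally symmetric
scaffold (midline landmarks in the x = 0 plane, paired landmarks mirrored
in x) then places exactly the defining pairs at those distances — the
inferior orbital edge comes from the sphere–sphere intersection of the V4
and Z1 constraints, with a clear error when the targets admit no
intersection.  The ten landmarks not pinned by any distance sit at fixed
scaffold positions scaled by V1; their placement is arbitrary but frozen
(version tag `scaffold-v1`), because GPA means depend on all 18 points.

P07 and P08 are not free once P01–P06 are fixed: the geometry forces
P07 = P01/P04 and P08 = P02/P01.  Precedence is P01–P06 over P08 over
P07, and `realized_proportion_targets` always reports what a scaffold will
actually measure.  For the shipped calibrations the forced P08 differs
from its nominal value by < 0.002 except the female cluster-1 column
(forced 1.719 vs nominal 1.746 — cluster means of ratios need not satisfy
the ratio identity); the forced P07 differs substantially everywhere, as
discussed under the measurement model.

Noise is i.i.d. Gaussian on every coordinate, default sd 0.5 mm — a
plausible digitisation error, on the order of the ~0.4 mm voxel spacing
of clinical CBCT.  Pose, when enabled, is a Haar-uniform rotation
(unit-quaternion sampling), uniform translation within ±500 mm per axis
and uniform scale in [0.8, 1.25].  All randomness flows from a single
seed.  Default cohort sizes are 46 male / 44 female, split evenly between
the two clusters of each sex (per-cluster counts for the reference cohort
are not published; the even split is a package choice).

What the simulator does not emulate: anatomically realistic surface
geometry, correlated (non-isotropic) landmark error, within-cluster
covariance between proportions, asymmetry, or age structure.  Passing
tests therefore demonstrate the correctness of the algorithms and the
recoverability of planted structure, not clinical validity on real CBCT
cohorts.  One visible consequence: because each simulated sex is an exact
two-cluster mixture, many sex × proportion cells fail the KS normality
screen on simulated cohorts, which real (noisier, more continuous)
cohorts typically pass.

The toy template meshes are inflated convex hulls of a scaffold's
landmark cloud, subdivided for density and annotated with the landmarks
as free points — synthetic stand-ins for CT-derived skull polygon models,
adequate for exercising and testing the morphing path.

## Problem sizes and tolerances

Simulated analyses use the reference cohort sizes (46/44, even cluster
splits).  Property suites use 18-point configurations throughout; the
null-calibration checks use 2,000 simulated Welch comparisons and 500
planted-FDR replicates; brute-force oracles run at small n (exhaustive
2-partitions at n = 6; black-box similarity-fit optimisation with
multi-start Nelder–Mead + BFGS polish).  Numerical contracts asserted in
tests: exact TPS interpolation to RMS 1e-8 and zero kernel weights (1e-10)
for affine maps; proper rotations to det = 1 ± 1e-10; GPA mean invariance
under input similarity transforms to 1e-6 Procrustes distance; proportion
similarity-invariance to 1e-10 relative.

## Limitations

- The proportion scheme's P05/P07 ambiguities (above) are resolved by
  documented defaults, not by external ground truth.
- KS-with-estimated-parameters is anticonservative; prefer the Lilliefors
  flag when the screen matters.
- The elbow suggestion is a heuristic; k is a user decision.
- TPS extrapolates linearly far from the control points; template meshes
  should roughly cover the landmark cloud.
- No tangent-space projection, semilandmarks, or PCA shape spaces.
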