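# Methods

This note documents the models implemented in `profilespace`, the design
choices that were genuinely open, the synthetic-data generator's assumptions,
and the numerical conventions. It states no empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Equivolumetric depth sampling

Intracortical surfaces are placed by volume fraction rather than by
Euclidean distance: with outer area `a_out`, inner area `a_in` and a
cross-sectional area that interpolates linearly between them, the surface
enclosing fraction `alpha` of the segment volume sits at

    rho(alpha) = (-a_in + sqrt(alpha*a_out^2 + (1-alpha)*a_in^2)) / (a_out - a_in)

measured from the inner boundary. `rho` is strictly increasing in `alpha`
and the enclosed volume up to `rho(alpha)` equals `alpha` of the total
exactly (the test suite verifies this against numeric integration).
When `|a_out - a_in| < 1e-9 * a_out` the continuous limit `rho = alpha` is
used. The default sampling grid is the 12 strictly interior fractions
`k/13`, matching the convention of placing surfaces *between* the pial and
white-matter boundaries; whether boundary-inclusive grids were used by any
given preprocessing pipeline is not recoverable from typical descriptions,
so the grid is configurable. Area pairs are inputs (per parcel or vertex);
the package does not re-derive fold geometry from meshes.

## Profile measures

Each subject × parcel depth profile is summarized by its mean and its
moment skewness `g1 = m3 / m2^1.5` (central moments with divisor n).
`g1` was chosen over bias-corrected variants because it is affine-invariant,
defined for the 12-sample profiles, and estimator choice is immaterial for
group *contrasts* (any monotone variant yields the same ordering).
Constant profiles receive skewness 0 plus a degeneracy flag rather than an
error, since a flat profile is a legitimate (if extreme) observation.
Skewness is min–max rescaled to [0, 1]; the scope of the rescaling is
per subject across parcels by default (so each subject's map spans the unit
interval and between-subject offset differences are removed), with a
group-wide option.

## MPC and gradients

The microstructural profile covariance between parcels i and j is the
partial correlation of their depth profiles controlling for the
cortex-average profile, averaged over subjects. Numerically this equals
correlating the residuals after regressing each profile on the global
profile; the test suite enforces agreement with that independent route to
1e-10.

Sparsification: entries ≤ 0 are zeroed, positive entries are Fisher-z
transformed (`0.5*ln((1+r)/(1-r))` — the conventional variance-stabilizing
"log transform" of correlations), and each row retains its
`ceil(0.10*(P-1))` largest off-diagonal entries (ties broken toward the
lower parcel index for determinism). Because any strictly increasing
transform of the positive entries leaves the retained set unchanged (tested
explicitly), the choice of transform affects stored edge weights only, and
the threshold/transform order is immaterial for which edges survive.
Row-wise (per-parcel) rather than global retention follows standard
gradient practice.

The affinity kernel is the normalized angle `1 - arccos(cos_sim)/pi` on
matrix rows; all-zero rows (parcels with no surviving similarities) are
flagged and isolated. Diffusion-map embedding uses anisotropic
normalization `W' = D^-0.5 W D^-0.5`, row-normalization to a Markov
operator, eigendecomposition through the symmetric conjugate, division by
the trivial eigenvector, and `lambda/(1-lambda)` scaling (automatic
diffusion time) — the defaults of the toolboxes this analysis style relies
on. If the affinity graph is disconnected, the leading unit eigenspace is
rotated so its first basis vector is the global stationary direction;
this makes the first returned component sign-separate the connected
components and is reported with a warning. Eigenvector sign is inherently
arbitrary, so the first gradient is oriented to correlate positively with
the group profile-mean map and the rest get a max-|entry|-positive
convention. Per-subject gradients are computed from single-subject MPC,
aligned to the group gradient by orthogonal Procrustes rotation (no
scaling), and the first aligned component is min–max rescaled per subject.

## Group statistics

The parcel-wise model is ordinary least squares of the measure on
`intercept + sex + age + ICV + euler_number` (female coded 1, so positive
t means higher in females), fitted mass-univariately with a shared design
matrix; p-values are two-sided from the t distribution with `n - k`
residual degrees of freedom, and the statsmodels OLS fit serves as the
independent oracle in tests. Family-structure random effects are out of
scope (fixed-effects only); a thickness covariate can be added. FDR is
Benjamini–Hochberg within one measure and one comparison map. Cohen's d is
obtained from t as `d = t*sqrt(1/n1 + 1/n2)`, the standard two-group
conversion, which preserves sign and is exact for the unadjusted two-sample
case.

Hormone-proxy groups bin naturally cycling (NC) females by self-reported
cycle day: high estrogen days 7–23 (mid-cycle), low estrogen days 0–6 and
24–28 (just before and during menstruation), low progesterone through day
14 (follicular), high progesterone from day 15 (luteal). The two binnings
overlap by design; oral-contraceptive (OC) users form their own group and
NC females without a usable day in [0, 28] join no subgroup. Boundary-day
conventions (inclusive at 7/23 and the 14/15 split) are fixed here and
exposed in the returned `day_windows`. Effect-size maps across comparisons
are compared by one-way ANOVA over parcels with Tukey HSD post hocs;
parcels are spatially autocorrelated, so these nominal p-values overstate
independence — the procedure replicates common practice and the caveat
applies to any use of it.

QC filtering excludes subjects deviating strictly more than 2.5 group SDs
on any summary metric (strict inequality: a subject exactly at the
threshold is retained); zero-variance metrics are skipped with a warning.

Split-half reliability partitions subjects into two disjoint halves with
preserved sex ratio (an odd count sends the extra subject to the first
half), fits the sex GLM per half, and correlates the unthresholded t-maps;
reported are the per-split r, its mean, and the 5th/95th percentiles.

## Spin permutations

Parcel-level maps are tested against spatial nulls by spherical rotation:
each permutation draws a Haar-uniform 3D rotation, applies it to the
left-hemisphere parcel centroids and the x-mirrored rotation to the right
hemisphere, and re-labels parcels by the minimum-cost assignment
(Hungarian algorithm) between rotated and original centroids within each
hemisphere. The assignment makes every permutation a true bijection — the
multiset of map values is conserved exactly — and reduces to the identity
for the identity rotation. Permutation p-values use the add-one rule
`p = (1 + #{null >= obs})/(1 + n_perm)`, bounded below by `1/(n_perm+1)`;
a raw-proportion convention differs by at most that bound. The phenotype
map is the one spun; gene and atlas maps stay fixed. One-sided tests (in
the observed direction) are the default for gene/type/vascular decoding,
two-sided is available.

Parcel-level spins are mildly liberal relative to exact rotations, because
re-labelling at parcel resolution slightly roughens the spun map; the
effect shrinks with parcellation resolution. The calibration experiment in
the validation suite therefore runs at 400 parcels — the resolution of a
standard whole-cortex parcellation — where the empirical size at nominal
0.05 sits within the acceptance band; vertex-level spins are out of scope.

Gene-set association uses the overall regression F of the phenotype on all
gene maps with spun-phenotype nulls; per-gene association uses Spearman
correlations with spin p-values, FDR-pooled over the full gene × measure
family. A baseline transcriptomic component (first principal component of
the standardized panel, sign-anchored to mean expression) provides a
specificity reference.

## Synthetic-data generator

The generator emulates the statistical structure of a large young-adult
surface-MRI cohort; it is plumbing with known ground truth, not MRI physics
(no bias fields, no volumetric synthesis).

*Geometry.* Each hemisphere is a full unit sphere (the registration-target
convention) with a jittered Fibonacci vertex lattice, convex-hull faces,
and spherical-Voronoi parcels around farthest-point-sampled centers —
quasi-uniform, spatially contiguous parcels at any requested resolution.
Smooth fields are white vertex noise diffused by k rounds of neighborhood
averaging and re-standardized; k (default 10) sets the correlation length.
An optional rectangular "unfolded hippocampus" grid with subfield bands
(Sub, CA1–CA4) reuses the same machinery for mean-only analyses; spins are
undefined on it.

*Cohort.* Defaults mirror the composition of the motivating cohort scale:
594 females (about 29% OC users; a third of the rest without a usable
cycle report; cycle days uniform on {0..28}) and 499 males, ages uniform
on 22–37, sex-specific lognormal intracranial volume, a Poisson-defect
Euler number, and a configurable twin fraction sharing family ids. ICV and
Euler distributions are plausibility placeholders (no public per-sex
distributions were adopted) and fully configurable; family structure is
generated but treated as an ignorable covariate.

*Profiles.* A subject's parcel profile is a monotone depth template
(T1w/T2w rising toward the white matter, default 1.2 → 1.8 across depths)
plus parcel-level smooth fields for baseline offset, profile slope and
curvature (the source of MPC structure), a subject intercept, a
subject-level smooth field, and i.i.d. vertex × depth noise. The noise
defaults (subject intercept SD 0.06, subject field SD 0.035, vertex noise
SD 0.15 in T1w/T2w units) put most between-subject variance in global
offsets, as in real T1w/T2w data where inter-subject intensity calibration
dominates. Vertex-level constructs are aggregated through the parcel map;
the i.i.d. term is drawn directly at parcel level with its exact
`N(0, sd^2/V_p)` aggregated law.

*Planted effects.* The sex shift at parcel p is `d_p * sigma_p`, where
`sigma_p` is the realized between-subject SD of that parcel's nuisance
components, so the planted Cohen's d is exact at population level under
the generator's own noise. Skewness effects add a zero-mean, depth-
asymmetric exponential-ramp shape whose amplitude is calibrated by a
finite-difference probe of the mean skewness response; the contract is
correct sign and ordering, not an exact skewness-d. Hormone modulation
multiplies the per-subject effect by `1 + m_p * h(subject)` with `h`
piecewise-constant over OC status and the four cycle-day bins 0–6, 7–14,
15–23, 24–28 — a binned design that makes per-bin recovery targets exact.

*Reference maps.* Coupled genes are
`c * z(effect map) + sqrt(1-c^2) * z(smooth field)`; uncoupled genes are
smooth fields; all pass through scaled-robust-sigmoid (SRS) normalization
(`sigmoid((x - median)/(IQR/1.35))`, then min–max). Note the min–max stage
necessarily shifts all outputs when an extreme value extends the observed
range — robustness to outliers holds at the sigmoid stage, and far exceeds
a mean/SD sigmoid. Cortical types are six quantile bins of a perturbed
latitudinal gradient; arterial/venous maps are independent smooth fields.

*What the generator does not emulate.* Real measurement artifacts
(B1 inhomogeneity, surface-reconstruction errors), realistic regional mean
maps, genuine family covariance, distance-dependent effect topographies
tied to anatomy, or transcriptomic covariance between genes. Passing the
recovery suites therefore demonstrates estimator correctness and
calibration under a known generative model, not robustness to all
real-data pathologies.

## Validation experiment sizes

`profilespace/validation.py` defines the experiments behind both the
acceptance tests and `scripts/acceptance.py`. Problem sizes are the
package's choice of the smallest scales at which the comparisons are
informative: algebraic oracles at 8–50 parcels; null GLM calibration from
2000 replicate fits (40,000 p-values); spin calibration with 999 spins and
1000 smooth-map pairs at 400 parcels; d-map recovery as the mean over five
replicates of an n = 400/400 cohort with d ∈ [0.2, 0.5] planted on 10% of
200 parcels; hormone-bin ordering over 100 generator seeds with 1000 NC
females, 400 males and planted subgroup means d = 0.2/0.4/0.6/0.8 (the
shared male-reference error cancels in the ordering comparison);
OC-specific recovery with the NC bins' modulation set to cancel the base
effect; split-half reliability with n = 500/500 and 200 splits — the null
regime as the mean over eight independent cohorts with an i.i.d. 400-parcel
noise measure, because for any single finite cohort the split-mean r
converges to a cohort-specific constant whose spread scales with the map's
effective degrees of freedom; and determinism by hashing every file of two
identically-seeded demo-pipeline runs. A single master seed derives
independent child seeds per experiment, all below 2^31.

## Known limitations

- Parcel-level spins carry the mild liberality discussed above; at coarse
  parcellations (≲100 parcels/hemisphere) empirical size can reach ~0.07
  at nominal 0.05.
- The effect-size ANOVA treats parcels as independent observations.
- Fixed-effects OLS only; related subjects are not modelled.
- The equivolumetric rule assumes linear area interpolation between
  boundaries, the standard local model; strongly curved segments deviate.
- `MPCMatrix` weights (not the retained edge set) depend on the
  threshold-vs-transform order convention documented above.
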