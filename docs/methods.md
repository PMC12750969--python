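# Methods

This note records the statistical procedures implemented in `vertmorph`, the
defaults and why they were chosen, what the synthetic generator does and does
not emulate, and the numerical decisions a maintainer would want written
down.  Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Data model and sampling protocol

The unit of observation is a 3D landmark configuration: one vertebra of one
specimen, 30 landmarks × 3 coordinates in arbitrary scanner units.  Presacral
columns are reduced to 10 homologous positions — first/middle/last vertebra
of the cervical (C1/C2 excluded, so candidates start at C3), thoracic and
lumbar regions, plus the diaphragmatic thoracic (TD).  For even regional
counts n the "middle" is the vertebra after the midpoint, index n/2 + 1.  TD
is observational metadata supplied per specimen, not computed: its anatomical
identification (the zygapophyseal transition) cannot be derived from counts.

Region-specific landmarking schemes are consolidated to a common 30-landmark
scheme by dropping, in 1-based indexing, landmarks 16, 17, 33, 34 from
34-landmark cervicals, 16, 17 from 32-landmark thoracics and 16–19, 35, 36
from 36-landmark lumbars, preserving the relative order of the rest.  This
makes serially homologous elements commensurable for multi-element analysis.

Species with multiple specimens are averaged.  By default the mean is taken
*after* superimposition: averaging raw configurations would conflate
digitizing orientation with shape.  A `species_mean_when: before_gpa` switch
exists for columns digitized in a common frame, since the alternative order
is defensible when orientations are controlled; the default is the safe one.

## Generalized Procrustes analysis

Configurations are centered, scaled to unit centroid size
(CS = √Σ‖x_j − x̄‖²), and iteratively rotated onto the consensus with the
sign-corrected Kabsch solution; reflections are never admitted (vertebrae
are chirally consistent), enforced by flipping the smallest singular
direction when det < 0.  The loop starts from the first configuration as
reference — a test asserts the result is invariant (in pairwise Procrustes
distances) to arbitrary pre-rotations of the inputs, so the choice is not an
assumption.  Convergence: Frobenius change of the (unit-rescaled) consensus
below `tol = 1e-8`, `max_iter = 100`, both configurable; on non-convergence
a partial result is returned flagged `converged=False`.  The stored
consensus is the plain arithmetic mean of the final aligned shapes, so the
documented invariant `consensus == aligned.mean(axis=0)` holds exactly.

Full Procrustes is used: sizes are removed and retained separately as the
centroid-size covariate.  No tangent-space projection is applied by default
— principal components are computed on aligned coordinates directly, the
within-sample dispersions involved being small enough that the tangent
approximation is excellent; an orthogonal-projection toggle
(`tangent_project=True`) exists because usage varies between packages in
this field and the original convention for any given dataset may differ.

One consequence worth knowing: the mean shape has centroid size slightly
below 1 (means of unit vectors lie inside the sphere).  An external
configuration equal to the consensus, pushed through the fossil-projection
path (which rescales to exactly unit size), therefore acquires a small
radial offset of order 1 − ‖M‖ instead of scoring exactly zero; the exact
zero holds when the mean shape is projected at its own scale.  The test
suite pins both facts.

## Shape spaces

Per-vertebra PCA is the eigendecomposition of the covariance (divisor
N − 1) of vectorized aligned shapes, retaining min(N − 1, 3k) components.
Eigenvector sign is fixed by making each vector's largest-magnitude loading
positive — an arbitrary but deterministic orientation that keeps regression
tests stable across BLAS backends.

Multi-element combination: each element is superimposed separately, its
vectorized shape matrix centered over the common specimens, optionally
divided by the square root of its total variance (so each block contributes
unit variance), and the blocks are concatenated column-wise for one global
PCA.  Scaling is on by default — without it, elements with more shape
variance dominate the combined morphospace, against the intent of a
consensus analysis — but it is a config switch (`scale_blocks`) because
multi-block normalization conventions differ between implementations and a
reference dataset may require the unscaled variant.  Only specimens present
in every block are used, in sorted-id order, which makes combined scores
independent of block input order.

## PERMANOVA

With squared distances d²_ij and groups of sizes n_g:

    SS_total  = Σ_{i<j} d²_ij / N
    SS_within = Σ_g Σ_{i<j∈g} d²_ij / n_g
    F = ((SS_total − SS_within)/(g − 1)) / (SS_within/(N − g))

Distances default to Euclidean on the vectorized Procrustes-aligned
coordinates (the tangent approximation of Procrustes distance); the exact
Procrustes metric is available via `metric="procrustes"`.  Inputs are
species means — one point per species — matching the downstream analyses.
p-values count permutations with F* ≥ F under random relabelling:
p = (1 + #exceed)/(1 + n_perm), default n_perm = 999.  Pairwise tests run on
the two-level subsets, each with an RNG stream derived as
`SeedSequence([seed, pair_index])` over lexicographically ordered pairs, so
a pair's result does not depend on which other levels exist.  Reported
significance uses a 0.005 threshold with no further multiplicity correction
(configurable); raw p-values are always written.

## Phylogenetic GLS

Brownian covariance: C_ij is the root-to-MRCA shared path length, computed
from root distances and patristic distances (C_ii is the root-to-tip depth).
Before inversion C is rescaled to unit determinant — pure conditioning, and
a test asserts R² and p are invariant to scalar rescaling.  The whitening
transform is the symmetric inverse square root from an eigendecomposition,
with eigenvalues floored at 1e-10 of the maximum (the documented jitter
tolerance); a genuinely singular C raises.

Both Y (species × coordinates) and the design are premultiplied by C^{−1/2}.
Categorical predictors expand to full-rank indicator contrasts tested as one
overall effect — one R² and p per predictor, not per level.  With
R0 the residual sum of squares of the transformed intercept-only model and
R1 that of the full model: R² = (R0 − R1)/R0 and
F = ((R0 − R1)/df_effect)/(R1/df_resid).  Significance is by RRPP: permute
the reduced-model residual rows, add back the reduced fit, recompute F;
999 permutations by default, same seeding conventions as PERMANOVA.  Speed,
hunting and log centroid size are fitted as separate models by default (a
combined model is a one-line change at the call site); the pipeline fits all
three per block.

Species missing from the tree are dropped with an explicit warning, never
silently, and the tree is pruned to the survivors.

## CVA and membership probabilities

CVA is fitted on the first k PC scores.  Default k: the smallest number of
PCs reaching 95% cumulative variance, capped at N − g − 1 so the pooled
within-group covariance stays invertible; always configurable, and every
report records the k used, because classification accuracies and fossil
probabilities are sensitive to this choice.  The canonical basis A solves
the between/within generalized eigenproblem via within-group whitening and
satisfies AᵀWA = I, so training canonical scores have identity pooled
within-group covariance (asserted to 1e-6) and canonical Euclidean distance
equals Mahalanobis distance in PC space.  Axis signs follow the same
largest-loading convention as the PCA.  Leave-one-out classification refits
the model without the held-out specimen; since removal can reduce a
two-member group to a singleton, the internal refit admits singleton groups
(they simply contribute nothing to W) while direct fits still require two
members per group.

Membership probability is the equal-prior posterior
p_g = exp(−d²_g/2)/Σ_h exp(−d²_h/2) — invariant to adding a constant to all
d², summing to one by construction.  The chi-square typicality
1 − CDF_{χ²(r)}(d²_g) is reported alongside: the posterior says which group
is *relatively* closest, the typicality whether the specimen is plausible
for that group at all, and a fossil outside the extant morphospace can have
a high posterior with a near-zero typicality.  Predictions with posterior
above 0.95 are flagged as strongly supported — a reporting convention, not
a computation.  Combined-element fossil predictions use the multi-block
space restricted to the positions the fossil preserves, then the same CVA
path.

## Synthetic generator

The generator emulates the statistical structure the analyses assume:

- a pure-birth (Yule) phylogeny, depth normalized to 1.  The birth process
  stops at the n-th speciation, which would leave two zero-length terminal
  branches and a singular C; every tip is therefore extended by a common
  increment of at least half a mean waiting time ((0.5 + Exp(1))/n), keeping
  the tree ultrametric with strictly positive terminal branches — mirroring
  species-level supertrees, whose shortest terminal branches are a few
  percent of tree depth;
- species mean shapes = base shape (a 30-landmark helix, unit centroid
  size) + Brownian deviates with covariance σ²_BM·C across species, i.i.d.
  across the 90 shape coordinates + additive group effect vectors;
- effect vectors are random unit directions orthogonalized against the
  translation and scale directions (pure shape effects), with magnitudes
  expressed in multiples of the within-group SD √(σ²_BM + σ²_noise);
- specimens add isotropic digitizing noise and receive a random proper
  rotation, translation and log-normal scale, so superimposition is
  genuinely exercised;
- pseudo-fossils are drawn at a group's population mean shape (base + its
  effect vector + the average effect of the orthogonal category) plus
  noise, and are never part of training.

Defaults, fixed once: 43 species, 10 positions, 30 landmarks, 3 speed and 4
hunting levels assigned in shuffled balance, σ²_BM = 5e-4 per coordinate
over unit depth (interspecific shape distances well above digitizing error,
as in real interfamilial data), noise SD 0.005 (≈0.5% of centroid size),
speed effects 3 within-group SD and hunting effects 1.5, one specimen per
species.

What the generator does **not** emulate — and hence what passing tests do
not demonstrate about real data: correlated evolution among landmarks
(deviates are i.i.d. per coordinate; real integration is structured),
covariation between vertebral positions along one column (positions draw
independent deviates), biomechanically realistic vertebral geometry,
unbalanced and correlated ecological categories (real speed and hunting
assignments are strongly associated), and non-Brownian evolution.  Because
measurement noise is white rather than C-structured, GLS whitening slightly
inflates effect sizes relative to a perfectly specified model — visible in
the synthetic null and equally present in any real analysis that ignores
measurement error.

## Numerical choices and degenerate inputs

- Degenerate configurations (all landmarks coincident) and empty datasets
  raise immediately; Morphologika parse errors name the offending line.
- Procrustes rotations use SVD with explicit determinant correction.
- `pseudo_f` returns ∞ when within-group dispersion is exactly zero with
  nonzero between-group separation.
- PCA of identical specimens returns all-zero eigenvalues and scores, with
  variance fractions reported as zeros rather than 0/0.
- Permutation p-values never drop below 1/(n_perm + 1); n_perm < 99 is
  rejected.
- All stochastic stages take integer seeds; the pipeline derives per-stage
  streams as `SeedSequence([seed, crc32(stage_name)])`, so removing one
  stage or position leaves every other output byte-identical.

## Problem sizes used in the shipped checks

The self-contained verification uses simulated studies of 18–43 species and
one to ten vertebral positions, 1000 null replicates (199 permutations
each) for PERMANOVA calibration, 500 for PGLS calibration, and 100 seeds
for end-to-end pseudo-fossil recovery — sizes at which the permutation
machinery is exercised thoroughly while the whole suite stays quick on a
single core.

## Known limitations

- No sliding semi-landmarks, bilateral-symmetry decomposition or
  missing-landmark estimation; configurations must be complete.
- PGLS assumes Brownian motion with a known tree; no Pagel's λ or OU
  estimation.
- No PERMDISP companion test: a significant PERMANOVA can reflect
  dispersion as well as location differences.
- Equal priors in the membership posterior; group-size-weighted priors are
  deliberately out of scope.
- The exact PC retention and multi-block normalization used by any given
  reference analysis may differ from the defaults here; both are exposed in
  the configuration, and reports always record the settings used.
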