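# Methods

This note records the statistical model, the numerical conventions, and the
design decisions behind wingmorph, in the order the pipeline applies them.

## Shape model and superimposition

A specimen is an ordered set of k planar landmarks; order encodes homology
and is never re-sorted. Centring and scaling to unit centroid size maps each
configuration to the preshape sphere; generalized Procrustes analysis (GPA)
then alternates (i) optimal proper rotation of every preshape onto the
current consensus with (ii) consensus re-estimation as the mean rescaled to
unit norm, until the consensus moves less than `tol` (default 1e-8, partial
Procrustes distance) or `max_iter` (100) is reached. The objective
Σᵢ‖xᵢ − c‖² is non-increasing under both steps, which the implementation
records per iteration and the tests assert.

Conventions, each chosen once:

* **Partial Procrustes / unit size throughout.** No residual per-specimen
  scale fitting during iterations. This is the common default of the
  standard superimposition tools for this workflow and keeps centroid size
  interpretable as the size variable that was removed.
* **No reflection fitting.** The rotation is constrained to det +1 (2×2 SVD
  with sign correction); mirror images are never silently un-mirrored.
  Handedness is handled explicitly at ingest: `reflect_configuration`
  negates x about the centroid, flips the side flag, and leaves landmark
  order unchanged (a permutation hook is exposed because some digitizing
  protocols re-index after reflection; the wing protocol emulated here does
  not appear to need one, so none is applied by default).
* **Deterministic gauge.** After convergence the whole aligned set is
  rotated so the consensus's major principal axis is horizontal, with the
  180° ambiguity resolved by the sign of the consensus's x-coordinate
  skewness (falling back to y). Repeated runs and arbitrarily repositioned
  inputs therefore produce identical aligned files, which is what makes the
  pipeline-level invariance tests meaningful at the 1e-9 level.
* **Numerical stability near zero distance.** Procrustes distances are
  computed by rotating and subtracting in the complex representation rather
  than via √(2 − 2cos ρ) or arccos of the Gram matrix; the latter lose half
  the significant digits for nearly identical shapes (an arccos cannot
  resolve ρ below ~1e-8), which matters for convergence checks and for the
  degenerate-variation guard in the adequacy test.

## Tangent projection and adequacy

Aligned preshapes x (unit norm) are orthogonally projected onto the
hyperplane tangent at the consensus c: x′ = x − (x·c − 1)c, and statistics
use the deviations x′ − c. For planar landmarks these rows span at most
2k − 4 dimensions (translation ×2, scale, rotation removed).

The adequacy check computes all n(n−1)/2 pairwise geodesic distances
ρ = 2 arcsin(d_partial/2) and the corresponding tangent Euclidean distances,
then reports the through-origin least-squares slope (Σeρ/Σρ²) and the
uncentred correlation. A regression with an intercept would not test
proportionality, which is the question being asked. At the generator's 1%
landmark noise the slope is ≈ 0.9997 and every pairwise tangent/ρ ratio
falls within [0.999, 1.001]; at 30% noise the slope degrades, as it should.

## Ordination and discrimination

PCA is the eigendecomposition of the column-mean-centred covariance
(via SVD), with axis signs fixed by making each axis's largest-magnitude
loading positive so outputs are reproducible.

Because raw tangent coordinates are rank-deficient by construction, LDA
always operates on retained PCs. The auto rule keeps components with
eigenvalue > 1e-10 × the largest, capped at min(p, n − G − 1); an integer
`n_components` overrides it. In the reduced space the model keeps per-group
means, the pooled within-group covariance with denominator n − G (checked
positive-definite at relative tolerance 1e-10, with an error instructing a
smaller dimension otherwise), and up to G − 1 canonical variate directions
from the generalized eigenproblem of between- versus within-group scatter.

Mahalanobis distances use a Cholesky solve of the pooled covariance;
posteriors are PP_g ∝ π_g exp(−MD_g²/2) evaluated in log space with a
log-sum-exp guard, so a point far from every group still yields a proper
probability vector. Priors default to group-size-proportional, with `equal`
available; the choice is recorded in every report. Exact posterior ties
(relative tolerance 1e-12) go to the first group in label order and are
flagged. Leave-one-out cross-validation refits the PCA reduction and the
discriminant in every fold; it does **not** re-run the superimposition per
fold, which is treated as upstream preprocessing — a documented limitation
shared with the standard practice this package follows.

Hit ratios are kept at full precision internally; per-group values are
displayed as integers and the overall ratio at two decimals, matching the
reporting convention of the reference study's tables.

## Assignment of unknowns

Default mode (`joint`): one GPA over reference ∪ unknowns, discriminant
space fitted on the reference rows only, unknowns pushed through the same
centring/PC/discriminant maps. `opa` mode instead aligns each unknown to
the fixed reference consensus; it exists because a joint superimposition
lets unknowns influence the consensus slightly, and the two modes agree on
the assigned group in well-separated cases (tested). MDs are computed in the
full retained-PC space and the dimension used is recorded in the report,
since assignment distances are only interpretable relative to it.

Replicates of one physical specimen are kept as independent rows and
summarized by modal vote with an agreement fraction; landmark averaging is
deliberately not the default. There is no novelty detection — the procedure
always assigns to some reference group — but a warning (and a per-replicate
flag) is raised when an unknown's minimum MD exceeds the 99th percentile of
the reference specimens' own within-group MDs. Note that replicate
digitizations legitimately trip this flag more often than reference
specimens do, because digitization error adds variance the pooled
within-group covariance does not contain; the flag is a prompt for
inspection, not a rejection rule.

## Synthetic data

The generator emulates exactly the structure the analysis assumes: a fixed
template (jittered elliptical arc, unit centroid size), per-group mean
shapes formed by adding a random displacement field of norm `effect_size`
projected orthogonal to the template's similarity directions (so the whole
effect survives superimposition), i.i.d. isotropic Gaussian landmark noise
(`noise_sd`), and a uniform random similarity transform per specimen
(rotation ±π, translation ±1, log-scale ±0.35). Replicate digitizations add
`digitization_sd` noise around one drawn specimen. All draws descend from
keyed `SeedSequence` streams: one per group (adding groups never perturbs
earlier groups) and one per replicate trial.

Default conditions: k = 18 landmarks and the reference study's 15 group
sizes (total 360). `noise_sd` = 0.01 (1% of centroid size) puts the data in
the small-variation regime the reference analysis demonstrably occupied
(its adequacy statistic was ≈ 1); `effect_size` = 0.05 makes between-group
mean separation five times the per-coordinate noise — strong but not
trivial discrimination; `digitization_sd` = 0.005 makes re-measuring a wing
about half as variable as true individual differences. The
parameter-recovery demonstrations ("separation tuned high") use
`effect_size` = 0.1, i.e. separation an order of magnitude above noise, for
which group recovery should be — and is — essentially perfect.

What the generator does *not* emulate: allometry (shape–size covariation),
correlated or landmark-specific error, within-group taxonomic substructure
(species within subfamilies), and digitizer bias (replicate error is
centred). Passing tests therefore show the machinery is correct under the
model's own assumptions, not that real wing data meet those assumptions.

A note on measuring recovered noise: superimposition absorbs 4 of the 2k
noise degrees of freedom, so the sample standard deviation of aligned
deviations underestimates `noise_sd` by the factor √((2k−4)/2k); the
law-of-large-numbers test applies this correction.

A "chance level" for classification with unequal group sizes is not a
single obvious number; wherever the package's tests assert chance-level
behaviour they compare the observed accuracy against the expected agreement
under row/column independence computed from the confusion matrix's own
marginals (the pₑ of Cohen's κ).

## File formats

TPS dialect: `LM=`, coordinate lines, `ID=`/`IMAGE=` (ID preferred),
`SCALE=` (multiplied into coordinates at ingest, divided back out on write
so read → write → read is the identity); `CURVES=`/`POINTS=` blocks are
skipped with a warning. A coordinate pair of exactly (−1, −1) — the
digitizers' missing-landmark sentinel — or any NaN is a hard error at read
time, because the pipeline has no missing-data procedure; arbitrary finite
negative coordinates are of course legal (centring and reflection produce
them routinely). Group labels are not a TPS concept and travel in a sidecar
CSV (`specimen_id,group,side`). Coordinates are written with the shortest
representation that round-trips the double exactly.

## Problem sizes

The shipped demonstrations use the study-scale configuration throughout:
360 reference wings × 18 landmarks, 100-specimen single-group samples for
the adequacy checks, 2000 specimens for the noise-recovery check, and 100
seeded trials of eight-replicate unknown recovery. The full test suite and
the acceptance script each run in well under a minute on one CPU.
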