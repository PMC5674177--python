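# Methods

## Shape model

A specimen is a configuration of *k* labelled landmarks in the plane
(default *k* = 18, the bee-forewing convention of vein intersections and
cell corners; landmark order encodes homology and is never re-sorted).
Shape is what remains after removing translation, size and orientation.

**Pre-shape.** Each configuration is centred and scaled to unit centroid
size (the square root of summed squared landmark distances to the
centroid). Centroid sizes are kept and reported; they are in physical
units when the TPS `SCALE=` factor is applied at read time (off by
default, since superimposition discards size anyway).

**Superimposition (GPA).** Iteratively: rotate every pre-shape onto the
current consensus by the least-squares optimal rotation (SVD of the 2×2
cross-covariance with determinant correction), recompute the consensus as
the arithmetic mean rescaled to unit size, repeat until the consensus
moves less than `tol` (default 1e-10, iteration cap 100). Only proper
rotations (det +1) are used: reflection is a genuine shape difference
here, because left and right wings are mirror images and digitisation
side-errors must surface, not vanish. Mirroring is an explicit upstream
operation (`tps.mirror`). For realistic within-taxon variation the
iteration converges in under 10 steps; for pathologically dispersed shapes
(variation spanning much of shape space) convergence is only geometric and
the result is returned with `converged=False` plus a warning.

Two deterministic tie-breaks make outputs bit-reproducible: the SVD sign
convention picks one rotation when the cross-covariance is rank-deficient
(with a warning), and after convergence the whole aligned set is rotated
so the consensus's first-to-second landmark axis points along +x.

**Distances and tangent space.** "Procrustes distance" means the partial
Procrustes distance: the Euclidean norm of the residual between two unit
pre-shapes after optimal rotation. This matches the Euclidean geometry of
the aligned coordinates, so the adequacy check below is self-consistent.
Tangent coordinates are the flattened aligned configurations with the
component along the (unit) consensus vector removed; the consensus maps to
zero and every tangent vector is orthogonal to it. The adequacy check
computes all pairwise Procrustes distances and tangent Euclidean
distances, the through-origin regression slope Σtᵢpᵢ/Σpᵢ² and the
product-moment correlation; both near 1 justify linear statistics in the
tangent plane (they are ≈ 0.9999+ at the 1% noise level typical of
congeneric wing variation).

## Discriminant model

Groups are taxa at one rank. The model is Gaussian with group-specific
means and a single pooled within-group covariance:

- Tangent vectors are reduced to the principal directions of total
  variance with relative variance above 1e-12. Superimposition leaves at
  least four exactly-null directions (2 translation, 1 size, 1 rotation)
  that would otherwise make the covariance singular. The retained
  dimension is additionally capped at n − G (specimens minus groups):
  total variance has rank up to n − 1 while the within-group scatter has
  rank at most n − G, so without the cap the pooled covariance is singular
  on any sample this small — the cap keeps the model defined whenever the
  data genuinely support it, and a singularity error then only signals
  degenerate data (e.g. zero within-group variance). The reduction map is
  stored so unknowns can be projected through it.
- Pooled covariance uses the n − G denominator; optional shrinkage
  λ toward its diagonal (default 0 = plain LDA) is available for tiny
  groups. Canonical axes solve the generalized between/within eigenproblem
  (at most G − 1 axes, largest-magnitude loading oriented positive).
- Priors: `equal` by default — reference collections are availability
  samples of taxa, and proportional priors would pull an unknown toward
  whichever groups happen to be densely sampled. `proportional` mode
  matches common statistical-package defaults.
- Scoring: MD_g = √((x−μ_g)ᵀΣ⁻¹(x−μ_g)) via Cholesky solves;
  pp = softmax(−MD²/2 + log prior). With equal priors, argmax posterior is
  exactly argmin Mahalanobis. Exact posterior ties are broken toward the
  lexicographically first group, with a warning.

**Cross-validation.** Leave-one-out: the discriminant model (including the
dimension reduction) is refitted without the held-out specimen, which is
then assigned by maximal posterior. The GPA alignment is *not* refitted
per fold — per-fold alignments would give each fold its own tangent space
and make folds incomparable; this matches standard morphometric practice.
Hit-ratios are reported per group and globally, as percentages, with the
G×G confusion table.

**A posteriori placement.** An unknown is pre-shaped, rotated onto the
*fixed* reference consensus, tangent-projected there, passed through the
stored reduction and scored. The hierarchical cascade runs superimposition
→ fit → placement independently for each (dataset, rank) stage, coarse to
fine; later stages are not gated on earlier outcomes, so the chain reports
evidence at every rank even when an intermediate assignment is ambiguous.

## Ordination

Covariance PCA (not correlation — tangent coordinates share units and
rescaling would distort shape geometry) of tangent coordinates about their
grand mean; numerically-zero-variance directions are dropped, percentages
are non-increasing and sum to 100, and full-rank scores preserve pairwise
tangent distances. Unknowns are projected onto the fitted axes without
refitting. Axis signs follow the largest-loading-positive convention.

## Synthetic data

The generator emulates the statistical structure the analysis assumes,
standing in for reference collections of digitised wings:

- a fixed, deterministic wing-like template (elongated closed outline with
  asymmetric low-order Fourier bumps; deliberately scalene and
  mirror-asymmetric so reflection errors are detectable);
- hierarchical group means: each taxonomic level adds an independent
  centred displacement field of magnitude `separation × within_sd ×
  level_scale` to its subtree, so sister groups share their parent's
  displacement; means are drawn once per seed, making the "taxa" stable
  fixtures;
- specimens: group mean + i.i.d. isotropic Gaussian landmark noise of
  standard deviation `within_sd` (a fraction of centroid size, default
  1%) — the simplest model consistent with the classifier's shared-
  covariance assumption — followed by a random similarity nuisance
  transform (rotation 0–2π, translation, log-scale ±0.7) that carries no
  shape information;
- unknowns: a draw from a chosen terminal group, optionally mirrored
  and/or sheared (x′ = x + shear·y before the nuisance transform) as a
  crude taphonomic-distortion model.

Defaults (k = 18, 3 coarse × 4 fine groups, 25 specimens per group,
`within_sd` = 0.01, `separation` = 10) give clearly separated but not
caricatured taxa: leave-one-out hit-ratios near 100%, assignment
posteriors near 1. What the generator does *not* emulate: landmark-level
covariance structure (allometry, integration of vein intersections),
unequal group covariances, digitisation error correlated across landmarks,
and unbalanced sampling. Passing tests therefore demonstrate that the
machinery is correct and well-behaved under the model's own assumptions —
not that any particular real collection is separable at these rates.

## Numerical choices and edge cases

- GPA: `tol` 1e-10 on consensus movement, `max_iter` 100; degenerate
  (zero-size) members are reported by specimen id.
- Pre-LDA variance cutoff 1e-12 (relative), dimension cap n − G (above).
- Coincident landmarks within a configuration and duplicate specimen ids
  are validation errors; 3-D TPS records (`LM3=`) are rejected since the
  pipeline is strictly planar.
- TPS coordinates are written with shortest round-tripping decimal
  representations, so write → read is bit-exact.
- Problem sizes in tests and in `scripts/acceptance.py` (n up to ~100
  specimens, 100 replicate unknowns) are chosen so every property is
  measured at stable statistical resolution while the whole suite runs in
  seconds; the statistics scale to thousand-specimen collections
  unchanged.

## Known limitations

- 2-D landmarks only; no semilandmarks, curves or sliding.
- Equal-covariance LDA only (no QDA); strongly heteroscedastic groups will
  inflate some groups' posteriors.
- The shear distortion model is affine and global; real taphonomic
  deformation can be local and nonlinear.
- The hierarchical cascade quantifies affinity to *sampled* groups; an
  unknown from an unsampled lineage will still be placed somewhere — the
  Mahalanobis distances, not the posteriors, are the guard against
  overconfident placement.
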