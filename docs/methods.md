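# Methods

This note documents the models and numerical choices behind `opermorph`,
module by module, and what the synthetic-data generator does and does not
emulate.

## Outline morphometrics

An opercle outline is a closed planar curve digitized as an ordered point
sequence (TPS format).  Analysis operates on *k* semilandmarks placed at
equal arc-length intervals along the piecewise-linear curve (default
k = 100), traversed clockwise (negative shoelace signed area) from a
homologous start point on the dorsal margin.  Two conventions for the
start point are supported:

* **index 0** (pipeline default): digitized outline records begin at the
  point the operator clicked first, which by protocol is the dorsal
  landmark.  This is the robust choice for real data.
* **curvature detection**: the vertex maximizing discrete curvature
  (absolute exterior turning angle divided by mean adjacent edge length)
  within the upper-y half of the outline, ties broken by lowest index.
  Vertex-level curvature is noise-dominated at realistic digitizing
  precision, so curvature is measured on a circularly smoothed copy of the
  outline (moving average, window ≈ k/20); even so, detection is intended
  for clean outlines and templates, not noisy specimens.

Superimposition is full generalized Procrustes analysis: center, scale to
unit centroid size, rotate to the running consensus by the Kabsch solution
with the reflection branch disabled (all specimens are same-side views),
re-estimate the consensus, iterate to a 1e-10 consensus displacement
(flagged, not raised, if the iteration cap is hit).  Semilandmarks are
fixed after resampling — no sliding by bending energy or Procrustes
distance; this matches protocols that resample once at digitizing time.
Tangent-space projection is taken as the identity, the usual
small-variation approximation; Procrustes distances between aligned
configurations are therefore Euclidean distances in coordinate space.

Shape PCA is an SVD of centered flattened coordinates (covariance, not
correlation — coordinates share a unit); form PCA appends ln CS.  At most
min(n − 1, 2k − 4) shape dimensions are nonzero (4 similarity degrees of
freedom are removed); the `effective_dim` property reports this.  PC signs
are fixed by making each axis's largest-magnitude loading positive.  The
broken-stick null proportion for axis j of p is
b_j = (1/p) Σ_{i=j..p} 1/i, with p the number of axes supplied; an axis is
flagged when its observed proportion exceeds b_j.

## Phylogenetic covariance and model transforms

For a rooted tree with branch lengths, C_ij is the shared root-to-MRCA
path length (C_ii the root-to-tip depth, T the maximum depth).  Candidate
trait-evolution models are covariance transforms:

| model  | V(θ) | bounds |
|--------|------|--------|
| BM     | C | — |
| WN     | I | — |
| λ      | off-diagonal × λ | [0, 1] |
| δ      | elementwise C^δ, rescaled so max diag = T | (0, 100] |
| EB     | (e^{aC} − 1)/a, limit C as a → 0 | [−20/T, 20/T] |
| OU     | e^{−2α(T−C)}(1 − e^{−2αC})/(2α) | [1e−8, 500] |

The δ transform is applied elementwise with height rescaling — equivalent
to the node-depth power transform on ultrametric trees and taken as the
convention otherwise.  OU uses the stationary (root-at-optimum) form on
the depth matrix, the common comparative-methods implementation.  The EB
rate-change parameter may be positive (acceleration); library conventions
that forbid this are deliberately not reproduced, since accelerating
evolution is a finding this machinery must be able to express.  Both
ultrametric and non-ultrametric inputs are accepted; T is always the
maximum tip depth.

## Likelihood, fitting and comparison

All fits are ML (not REML).  For trait vector x,

lnL = −½ [n ln 2π + ln|σ²V| + (x − z₀1)ᵀ(σ²V)⁻¹(x − z₀1)],

with z₀ and σ² profiled analytically (ẑ₀ the GLS mean, σ̂² = rᵀV⁻¹r/n) and
the remaining scalar parameter optimized by bounded Brent from a 5-point
grid of restarts plus explicit evaluation of both bounds; estimates within
1e−6 of a bound are flagged `at_bound`.  Parameter counts are 2 (BM, WN)
and 3 (transform models); AICc = 2k − 2lnL + 2k(k+1)/(n−k−1), with
Δᵢ = AICcᵢ − min AICc and weights e^{−Δᵢ/2}/Σe^{−Δⱼ/2}.  Solves use
Cholesky factorization throughout; a singular V (duplicate zero-length
tips) raises an informative error.

Blomberg's K uses the ratio form
K = [(MSE₀/MSE)_obs] / [(tr C − n/(1ᵀC⁻¹1))/(n−1)], with MSE₀ the mean
squared deviation from the GLS mean and MSE its C⁻¹-weighted counterpart;
K = 1 exactly on star trees.  The permutation P shuffles tip values with a
seeded generator and counts permutations with MSE ≤ observed (add-one
rule), so P ≥ 1/(n_perm + 1).  Pagel's λ signal is the ML λ fit.

BM ancestral states are GLS conditional expectations,
E[node|tips] = z₀ + c_vᵀC⁻¹(x − z₀1) with c_v the node-tip MRCA depths;
the root equals ẑ₀.  The evolutionary rate matrix is the GLS estimator
R̂ = (X − 1âᵀ)ᵀC⁻¹(X − 1âᵀ)/(n − 1), algebraically equal to the mean outer
product of standardized independent contrasts (the test suite verifies
this equivalence against a Felsenstein-pruning oracle).  Multivariate BM
simulation walks root-to-tip, adding N(0, R·len) increments per branch;
one child generator is spawned per replicate index, so replicate i is
identical no matter how many replicates are drawn.

## PGLS

Residuals follow BM on the tree (fixed C; no concurrent λ estimation, per
the neutral-residual assumption).  Species with missing values are dropped
pairwise and the tree pruned to the remainder before fitting.  Standard
errors use σ̂² = RSS_GLS/(n − p); P-values are two-sided t.  The reported
"correlation" is sign(β̂) · √R²_GLS with R²_GLS = 1 − RSS/TSS about the
phylogenetic mean — documented here because the quantity is conventional
in this literature but rarely defined.

## CVA and Procrustes ANOVA

Raw shape coordinates are rank-deficient, so CVA first projects onto
leading PCs (default min(n − g, 30, rank)), then solves the symmetric
generalized eigenproblem B v = ℓ W v (W pooled within-group with divisor
n − g, B between-group).  At most g − 1 axes are returned with
eigenvalue-share percentages.  Scores are invariant (to sign) under any
invertible linear transform of the feature space.

Procrustes ANOVA partitions squared tangent-space distances:
SS_B = Σ n_g‖mean_g − grand‖², F Goodall-type.  Inference is by
unrestricted random permutation of group labels (no exchangeability
restriction, as no blocking structure exists), add-one rule.  Shape and
ln CS are analyzed as two separate rows.

## Convergence (distance-contrast) test

For every species pair: observed Euclidean distance in the retained PC
space; patristic distance; and a simulated-distance sample from n_sims BM
simulations using R̂ and the GLS root state.  The per-pair lower-95% bound
is the bootstrap estimate (mean over n_boot resamples of the simulation
replicates) of the 2.5th percentile of that pair's simulated-distance
distribution; a pair is convergent when its observed distance falls below
the bound, so the two-sided null expectation is 2.5% of pairs.  The bound
is per pair rather than global: pairs differ greatly in expected distance,
and one global threshold would conflate them.  Morphological distance
operates on PC scores (equal to Procrustes distance between mean shapes
when all axes are retained); the number of retained axes is a logged
configuration choice.

## Disparity through time and MDI

Disparity of a species set is the mean squared pairwise Euclidean
distance.  The DTT curve is evaluated at each internal-node time t
(relative, root 0 to tips 1): the mean over every lineage crossing
immediately after t — edges with depth(parent) ≤ t < depth(child) — of its
subclade disparity divided by whole-clade disparity; single-tip lineages
contribute 0, and the root point is 1 by definition.  Curves are step
functions between node times; MDI integrates observed minus the
simulation median over [0, cutoff] on that step grid (cutoff 0.9, trimming
the tip-dispersion region).  The envelope is the per-time 2.5/97.5
percentile band of the simulated curves.  P is two-sided: twice the
fraction of simulations whose own MDI (about the same median) is at least
as extreme as the observed, capped at 1.

## Synthetic data: what it emulates, and what it does not

The generator mirrors the structure of an opercle-shape study: a pure-birth
tree rescaled to height 1 (54 species by default), an opercle-like
template (egg-shaped closed curve with a single dorsal curvature maximum
as the homologous start point), and latent shape axes evolved on the tree —
by default a BM axis (σ² = 0.04), a tips-concentrated δ = 3 axis
(σ² = 0.015) and a λ = 0.8 axis (σ² = 0.006), echoing the mixed model
support typically reported for shape axes.  Latent scores displace the
boundary along orthonormal sinusoidal normal-displacement modes starting
at boundary frequency 2 — the frequency-1 mode is translation-like and
would be silently absorbed by Procrustes centering — and orthogonalized
against the template's similarity-transform subspace, so planted axes are
pure shape.  Displacements large enough to fold the outline are clipped
with a warning.

Specimens (416 total by default, 5–10 per species) scale the species shape
by a log-normal centroid size whose log evolves by BM on the tree
(optionally coupled to a latent axis, giving allometry) and add isotropic
coordinate noise of sd 0.003 relative to the outline radius — about 1–2 px
on a typical photograph.  Noise enters shape space twice: directly, and
through arc-length resampling, where perimeter perturbations shift
semilandmarks tangentially; at much higher noise this tangential term
dominates planted signal, which is a property of real outline protocols
too, not an artifact.  Covariates are slope × latent + BM residual, with
gill-raker counts rounded at zero and ER/GLTL kept positive via a
log-linear link (slopes act on the log scale).  Feeding groups are
assigned as contiguous clade blocks (preference) or at random (mode), with
optional planted mean shifts along a basis mode.

Not emulated: image acquisition and segmentation, biomechanical
constraints on opercle form, within-species phylogeographic structure,
measurement covariance between traits, and non-ultrametric fossil tips.
Passing tests on these data therefore demonstrate correctness and
calibration of the estimators, not that any biological conclusion about
real cichlids transfers.

## Problem sizes and determinism

Every stochastic routine takes a seed; per-replicate generator spawning
makes simulation replicates order-independent, and a full pipeline run is
byte-reproducible for a fixed configuration.  The test suite exercises
calibration at the sizes its claims require (e.g. 200 BM replicates at
n = 128 for K; 100 replicates at n = 200 for λ and PGLS recovery; 500
null replicates for type-I error; 50 replicates of 500 simulations for
MDI).  The acceptance script runs the study-scale pipeline at n_sims =
1000 and reduces replicate counts moderately (10 convergence, 30 MDI
replicates), sizes chosen to keep a full from-scratch reproduction quick
on a single CPU while leaving Monte-Carlo error well inside the bands the
statistics are judged against.

## Known limitations

* No sliding semilandmarks; outline correspondence rests entirely on the
  start point and arc-length spacing.
* Single-optimum OU only; no multi-regime models or measurement-error
  terms in the trait models.
* Blomberg's K is attenuated by within-species/measurement noise (visible
  in the end-to-end synthetic study, where species-mean noise lowers K
  while λ stays high); the package reports what the estimator sees.
* The δ transform's elementwise-power convention on non-ultrametric trees
  is one of several in circulation; comparisons across software should fix
  the convention first.
* CVA assumes a shared within-group covariance; with very uneven group
  sizes the PC-retention rule, not the data, can limit the axes.
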