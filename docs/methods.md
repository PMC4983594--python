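# Methods

This note documents the models, algorithms, numerical conventions and
design choices behind `opermorph`, and what the synthetic-data generator
does and does not emulate.

## Landmark data and conventions

An outline configuration is k ordered 2D points (default k = 100) with a
single fixed Type-2 landmark (index 0), the curvature maximum on the
ventral anterior edge of the opercle; the other k − 1 points are sliding
semilandmarks placed equidistantly by arc length around the closed outline.
TPS files follow the tpsDig dialect (`LM=`, coordinate rows, `ID=`,
`IMAGE=`, `SCALE=`); coordinates are y-up and the reader performs no image
origin flip. A missing `SCALE=` means 1.0. Start points passed to the
resampler are always snapped to the nearest point on the curve (digitizing
clicks are never exact), with no distance threshold.

Right-side configurations are mirrored about the vertical axis through
their centroid and their traversal order is reversed (fixed landmark kept
in place) before any joint analysis, so tangent neighbors used in sliding
are consistent across sides. Reflection is an involution and is the only
place handedness changes: the Procrustes rotation itself is restricted to
det +1.

## Superimposition

GPA iterates: center, scale to unit centroid size, rotate each
configuration onto the running consensus (Kabsch with det +1), recompute
the consensus (mean re-scaled to unit size) until the consensus moves less
than 1e-10 (root summed squared difference) or 100 iterations. Aligned
shapes are optionally (default on) projected orthogonally into the tangent
space at the consensus, since downstream covariance analyses assume a
linear space. This is partial Procrustes: no scaling to cos(ρ).

The bending-energy model uses the kernel U(r) = r² log r (not r² log r²;
the two differ by a global factor of 2, which cannot change any sliding
minimizer — the convention is fixed here so energies are comparable across
runs). Duplicate or collinear reference landmarks are rejected.

Sliding runs an outer loop: GPA → bending-energy matrix B from the current
consensus → for every specimen, move each slider along its unit tangent
(from outline neighbors i−1, i+1, wrapping for closed outlines) by the
minimum-bending-energy displacement t* = −(TᵀET)⁻¹TᵀE(y − ȳ) → GPA again;
at most 10 outer iterations. Per sliding step the bending energy relative
to the consensus cannot increase (t = 0 is feasible), and this is asserted
in tests. A slider whose neighbors coincide has no tangent and is frozen
for that iteration with a warning; a numerically singular sliding system
falls back to the pseudoinverse.

**Convergence caveat.** The outer loop couples three moving quantities
(specimen parameterizations, the consensus, and B), and bending-energy
sliding of a closed outline with one fixed landmark has an energy-neutral
direction — all semilandmarks migrating coherently along the curve is
nearly affine and costs nothing. The coupled iteration therefore drifts
slowly along that manifold (empirically at a rate quadratic in the shape
deviation from the consensus: ~3e-3 per iteration at deviation 0.05,
~3e-5 at 0.005) and does not settle to the 1e-8 consensus tolerance except
for degenerate (identical-shape) data. The 10-iteration cap is what bounds
both cost and drift; the `converged` flag reports the truth. This mirrors
how the standard tools behave — they stop on much looser criteria after a
handful of iterations.

## Shape statistics

*Procrustes ANOVA.* Sequential decomposition: SS(individual) and SS(side)
from factor-level means around the grand mean, residual (the
individual × side interaction) by subtraction from the total. Degrees of
freedom are the univariate ones multiplied by the shape dimension 2k − 4;
F is the Goodall-style MS(effect)/MS(residual) with a parametric P from
the F distribution and an optional label-permutation P. Both specimen and
side are tested against the interaction residual; rows are labeled
"between-specimen" and "within-specimen". The design may be unbalanced
(one- or two-sided specimens).

*Allometry.* Shapes and centroid sizes are centered within species; the
common slope is b = Σ s̃ᵢỹᵢ / Σ s̃ᵢ². Raw centroid size is the default
regressor (log size available as an option). Groups with fewer than two
members or zero size variance are centered but excluded from slope
estimation, with a warning. Residuals are observed minus the common-slope
prediction and retain group mean differences, because the downstream
ordinations must still separate species and habitats. percent_predicted =
100·‖predicted‖²/‖within-centered shapes‖². The optional permutation test
shuffles sizes within groups.

*PCA* eigen-decomposes the sample covariance (divisor n − 1) via SVD;
axes below 1e-12 of the leading eigenvalue are dropped, and axis signs are
fixed so each axis's largest-magnitude loading is positive (determinism).

*CVA.* Data are first projected onto principal axes with nonzero variance;
the generalized eigenproblem B a = λ W a uses the pooled within-group
covariance (divisor n − g) and the n_j-weighted between-group covariance
(divisor g − 1). min(g − 1, rank) axes are kept and scaled so aᵀWa = 1
(unit within-group score variance). A singular W triggers rank reduction
with a warning.

*Group distances.* Mahalanobis distances use the pooled W in the projected
space. Because W has only n − g degrees of freedom, the projection is
capped at n − g − 1 leading principal dimensions (a label-independent cap,
so observed and permuted statistics live in the same space); at
museum-scale sample sizes the cap is inactive. Procrustes distances are
Euclidean norms of group-mean differences in the original space. Per pair
of groups, members are randomly reassigned (sizes preserved) and
P = (#{permuted ≥ observed} + 1)/n_perm, clamped to 1 — the observed
arrangement is counted, so the floor at 1000 rounds is 0.001, and no
"< 0.0001"-style strings are ever reported.

## Phylogenetic comparative methods

Species mean shapes (no re-superimposition of means; plain averaging of
aligned coordinates, with an option to re-superimpose) are matched to tree
tips; a merge map may pool several nominal species onto one tip (their
rows are averaged), unmatched tips are pruned and reported, unmatched
species are an error.

*Ancestral states* minimize Σ_branches ‖z_parent − z_child‖²/ℓ — weighted
squared-change parsimony, the Brownian ML reconstruction — solved through
the graph Laplacian with edge weights 1/ℓ (zero-length branches are nudged
to 1e-8 with a warning). The minimized objective itself is obtained from
the Schur complement of the Laplacian's internal block, a single s × s
quadratic form, which makes the permutation test cheap: each of the
n_perm − 1 rounds permutes tip rows and evaluates tr(ZᵀSZ).
P = (#{permuted ≤ observed} + 1)/n_perm. An unweighted variant of the
statistic (Σ‖Δ‖², all branch lengths treated as 1) can be had by passing a
tree with unit branch lengths.

*Pagel's λ* is fitted per ordination axis (univariate; no multivariate λ).
C holds shared root-to-tip path lengths; C(λ) scales off-diagonals by λ
with diagonals unchanged. μ̂(λ) and σ̂²(λ) have closed forms (GLS mean, ML
variance with divisor s), leaving a 1D profile likelihood maximized on
[0, 1] by bounded search (tol 1e-6), with an explicit snap to a boundary
when the optimum is flat against it — this makes "λ̂ = 1 ⇒ LR = 0 ⇒
P(vs 1) = 1" exact rather than approximate. Likelihood-ratio P values
against both λ = 0 and λ = 1 come from the χ²(1) upper tail; at a boundary
the χ² reference is conservative (the standard caveat). The λ = 0 profile
log-likelihood equals the i.i.d.-normal closed form, which is checked in
tests. The search is capped at 1 even where C(λ > 1) would remain positive
definite.

*Phylomorphospace* is a pure data product: tip coordinates are the species
scores, internal nodes the ancestral reconstructions, plus the
(parent, child) branch segments; no drawing is done here.

## Synthetic-data generator

The generator emulates the sampling design of a museum study: ~20 species
on an ultrametric Yule tree (scaled to unit depth; the pure-birth process
is run one extra exponential waiting time past the last speciation so tip
branches are never zero), ~13 specimens per species, two sides per
specimen with a configurable fraction of one-sided specimens, 100-point
closed outlines.

Outlines are radial Fourier curves r(θ) = 1 + Σ_h (a_h cos hθ + b_h sin hθ)
(8 harmonics) around a fixed smooth opercle-like base, multiplied by a
fixed sharp notch (depth 0.12, angular sharpness 40) on the lower-left
("ventral anterior") arc. The notch does not evolve: it is the anatomical
anchor whose concave curvature extremum defines the fixed landmark, found
on the dense 2000-point curve by signed discrete curvature with parabolic
sub-gridpoint refinement. Two generator details exist purely to keep that
anchor identifiable, as it is in real bones: (1) all random coefficient
deviations are weighted 1/h per harmonic, since the curvature of harmonic
h grows as h² and unweighted high-harmonic noise would out-spike the
notch (and make outlines implausibly wiggly); (2) the landmark is the
concavity extremum, not the |curvature| maximum, because the notch's
convex shoulders rival its center in absolute curvature.

Effect structure, applied in order: species mean coefficients = base + BM
deviations (variance `bm_rate`·branch length per unit-weighted dimension);
habitat stretch x·(1+δ), y/(1+δ) applied to the dense polyline of
freshwater species (δ/2 for brackish) *before* resampling, so landmarks
shift realistically with arc length; per-specimen lognormal size and an
allometric coefficient shift β·(size term)·v along a fixed unit direction
on harmonics ≥ 2 (h = 1 radial terms are near-translations and would be
absorbed by centering); a directional side-asymmetry offset ± noise; the
right side mirrored as a digitized right opercle would be; digitization
noise (isotropic, ∝ size) added to the final landmarks. The allometric
size term uses log size by default — an intentional, documented mismatch
knob against the raw-size analysis default; raw-size mode exists for
exact-recovery tests, where sizes of order 1 (size_meanlog = 0) keep the
slope's units sensible. Coefficient draws whose radius would fall below
0.15 are rejected and redrawn (rare at default rates: < 0.2%).

Identical config + seed give byte-identical TPS/CSV/Newick/JSON outputs.

What the generator does **not** emulate: digitizing error correlated along
the outline, within-species habitat differences (habitat is assigned per
species), non-Brownian evolution, measurement error in the tree, shape
asymmetry beyond a global directional offset, and any pixel-level image
effects. Passing recovery tests therefore demonstrates correctness of the
statistical machinery under the stated model, not robustness to every
property of real museum data.

## Problem sizes used in tests and the acceptance script

Unit tests run on small configurations (k = 12–48, n = 2–60). The
calibration studies use: 200 replicates × 16 tips (phylogenetic-signal
type-I, 200 permutations each, via the Schur-complement form), 500 null
datasets × 30 observations (distance-test type-I), 200 replicates of the
λ̂ recovery on a 64-tip tree, 100 generator-level λ̂ replicates at 16
species, 200 generator-level null datasets for the habitat-P uniformity
check, and one end-to-end run at the generator's default sampling sizes
(20 species × 13 specimens, k = 100, ~512 configurations) for the habitat
effect detection. These sizes were chosen so each study estimates its rate
with a standard error comfortably inside the asserted band.

## Known limitations

* Sliding uses the bending-energy criterion only (per the underlying
  workflow); Procrustes-distance sliding is not implemented.
* The sliding outer loop's honest convergence behavior is discussed above.
* 2D only; no curve+surface semilandmark hierarchies.
* No phylogenetic MANOVA / pGLS of full shape on habitat, no
  discriminant cross-validation, no multivariate λ.
* χ²(1) reference for λ boundary tests is conservative.
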