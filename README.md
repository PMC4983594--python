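# opermorph

Sliding-semilandmark geometric morphometrics and phylogenetic comparative
statistics for 2D bone outlines, built around the classic workflow used to
study opercle (gill-cover bone) shape evolution in fishes that move between
freshwater, brackish and marine habitats.

The package is aimed at morphometricians and fish systematists who digitize
closed bone outlines (one fixed Type-2 landmark plus equidistant sliding
semilandmarks), and want a scripted, reproducible version of the analysis
chain usually spread across tpsUtil/tpsDig, geomorph and MorphoJ:

1. **Landmark I/O** — TPS files, classifier tables (specimen, species, side,
   habitat `f`/`b`/`m`, locality), equidistant resampling of digitized
   outlines, reflection of right-side configurations to left orientation.
2. **Superimposition** — generalized Procrustes analysis (GPA) with
   semilandmarks sliding along their outline tangents to minimize
   thin-plate-spline bending energy against the consensus.
3. **Shape statistics** — Procrustes ANOVA of sides within specimens,
   side averaging, pooled within-species regression of shape on centroid
   size (allometric correction), PCA, shape reconstruction along axes,
   canonical variate analysis (CVA) of habitat groups with Mahalanobis and
   Procrustes distances and permutation tests.
4. **Phylogenetic comparative methods** — species means matched to a
   time-calibrated tree, phylomorphospace coordinates, ancestral shape
   reconstruction by branch-length-weighted squared-change parsimony,
   a permutation test of phylogenetic signal based on tree length, and
   maximum-likelihood Pagel's λ per ordination axis.
5. **Synthetic data** — a generator that emulates the whole sampling design
   (Brownian shape evolution on a Yule tree, habitat stretch, allometry,
   side asymmetry, digitization noise) and writes TPS/CSV/Newick files with
   ground truth, so every stage can be exercised and validated without any
   museum data.

## The statistics in brief

* **Centroid size** `CS = sqrt(Σᵢ ‖xᵢ − x̄‖²)`; GPA removes translation,
  scale (unit CS) and rotation (det +1 only), with optional orthogonal
  projection into the tangent space at the consensus.
* **Bending energy**: for a reference configuration, the thin-plate-spline
  kernel `U(r) = r² log r` is assembled into the bordered system
  `L = [[K, Q], [Qᵀ, 0]]`, `Q = [1 | x | y]`; the upper-left block `B` of
  `L⁻¹` gives the energy `txᵀB tx + tyᵀB ty` of a target `(tx, ty)`.
  Semilandmarks slide along outline tangents `uᵢ` by
  `t* = −(TᵀET)⁻¹TᵀE(y − ȳ)` with `E = diag(B, B)`, which never increases
  the bending energy to the consensus.
* **Procrustes ANOVA**: shape sums of squares over specimens and sides,
  Goodall-style `F = MS_effect / MS_residual` with degrees of freedom
  scaled by the shape-space dimension `2k − 4`.
* **Allometry**: pooled within-group slope `b = Σ s̃ᵢỹᵢ / Σ s̃ᵢ²` of
  within-group-centered shape on centroid size; residuals keep group means.
* **CVA**: generalized eigenproblem `Ba = λWa` with pooled within-group
  covariance `W` (divisor n − g) and between-group covariance `B`
  (divisor g − 1); at most g − 1 axes, scaled so `aᵀWa = 1`.
  Mahalanobis distance `D = sqrt(d̄ᵀW⁻¹d̄)`; permutation P values use the
  rule `P = (#{permuted ≥ observed} + 1)/n_perm`, so the smallest
  reportable P at 1000 rounds is 0.001.
* **Phylogenetic signal**: the statistic is the minimized tree length
  `Σ_branches ‖Δz‖²/ℓ` (weighted squared-change parsimony, the Brownian ML
  criterion); tip values are permuted across tips and
  `P = (#{permuted ≤ observed} + 1)/n_perm`.
* **Pagel's λ** scales the off-diagonal entries of the Brownian covariance
  `C` (shared root-to-tip path lengths); μ and σ² are profiled out in
  closed form and λ is found on [0, 1] by bounded search, with
  likelihood-ratio tests against λ = 0 and λ = 1.

## Worked example

Simulate a small dataset (8 species, 5 specimens each, 100 landmarks,
habitat stretch δ = 0.12) and run the full pipeline:

```python
from opermorph import RunConfig, run_pipeline
from opermorph.simulate import SimulationConfig

report = run_pipeline(RunConfig(
    simulate=SimulationConfig(n_species=8, n_specimens_per_species=5,
                              k_landmarks=100, habitat_effect=0.12, seed=7),
    out_dir="example_run", seed=7, n_perm=1000,
))
```

or, equivalently, from the shell: `opermorph pipeline --out example_run --seed 7`.

With this seed the run report prints (rounded):

```
Procrustes ANOVA   between-specimen SS 0.3601 (F 5652.1), within-specimen SS 0.0008 (F 463.7)
allometry          10.2% of within-species shape variance predicted by size (P = 0.001)
PCA                PC1-PC4: 64.3, 22.5, 6.2, 3.6 % of variance
phylo signal       tree length 0.136, P = 0.504
Pagel's lambda     PC1: 0.40 (P vs 0: 0.36, P vs 1: 0.008); PC2: 0.50
CVA                2 canonical variates, 91.1 / 8.9 % of between-group variance
habitat distances  f-m Procrustes 0.1264 (P = 0.001), Mahalanobis 310.0 (P = 0.001)
```

Reading: sides differ far less than specimens do (ANOVA), a modest share of
within-species variation is size-linked, and the freshwater–marine contrast
is highly significant in both distance metrics even though, with only 8
species and habitat cutting across the tree, the phylogenetic-signal test
stays non-significant. Mahalanobis magnitudes in runs this small are
limited by the within-group degrees of freedom (the pipeline warns and
reduces dimensionality accordingly); the Procrustes distances are the
stable effect-size measure.

All stage outputs are CSV files in `example_run/` (`pc_scores.csv`,
`cv_scores.csv`, `habitat_distances.csv`, `pagels_lambda.csv`,
`phylomorphospace_nodes.csv`, ...) plus a JSON `run_report.json` recording
seeds, conventions and timings.

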