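# Methods

## The model

Multi-subject spatial ICA treats each subject's demeaned fMRI run as a
time-by-voxel matrix `Y_ij` (subject `i`, group `j`) generated as `Y = A S`,
where the rows of `S` are spatially independent component maps and the
columns of `A` are their time courses. For a two-group comparison the
aggregate mixing matrix has a block structure: *shared* components load on
both groups' data, while a component *specific* to group 1 has (near) zero
mixing weights on group 2's block, and symmetrically. The decomposition
therefore both extracts components and classifies them, and the specific
components are the data-driven between-group difference patterns.

Estimation runs on a three-level linear reduction:

1. **Subject level** (`F_ij`): PCA of each subject's series onto its top
   temporal directions. Projection only — whitening is deferred, which
   keeps `F` well-conditioned.
2. **Group level** (`H_j`): the temporally concatenated subject-reduced
   data of each group is PCA-reduced to `Ng_j` dimensions *and whitened*
   (identity covariance across voxels). Subject order does not affect the
   retained subspace.
3. **Aggregate level** (`G`): the two groups' whitened matrices are stacked
   row-wise and whitened again down to `N` rows, the number of components.

Each level stores its Moore–Penrose back-projector, so group results can be
carried back to single subjects (below). Covariances are always estimated
across voxels with divisor `M − 1`; eigenvector signs are fixed by making
the largest-magnitude entry positive, so repeated fits are bit-identical.

### Why the group constraint is linear in the unmixing rows

On white aggregate data the unmixing matrix `W` is orthonormal and the
aggregate mixing matrix is `A = Wᵀ`, so the mixing column of component `c`
*is* its unmixing row `w_c`. Expressed in level-2 coordinates through the
aggregate back-projector `G⁺`, the "zero opposite block" requirement
becomes a linear constraint `C_opp w_c = 0`, with `C_opp` the opposite
group's row block of `G⁺`. The feasible subspace for group-1-specific
components, `null(C_g2)`, has dimension exactly `N − Ng2` — which is the
model's cap `M1` on how many group-1-specific components can exist
(symmetrically `M2 = N − Ng1`).

An important corollary that shaped the experiment designs: if a group
*claims all* `N − Ng` feasible dimensions, an orthonormal and fully
feasible unmixing matrix exists only if the two groups' feasible subspaces
happen to be exactly orthogonal, which finite data never provides. The caps
are an upper bound, not a target; the number of *allowed* specifics should
stay strictly below `N − Ng` whenever possible.

## The constrained fixed point

The fit alternates three steps until the rotation between successive
unmixing matrices falls below `convergence_tol`:

1. **Symmetric FastICA update** (tanh contrast by default):
   `w ← E[X g(wᵀX)] − E[g′(wᵀX)] w` for every row, followed by symmetric
   orthogonalization `W ← (WWᵀ)^(−1/2} W`. When the data hold fewer
   non-Gaussian directions than rows, a linear combination of updated rows
   can collapse; the inverse square root is then regularized with an
   eigenvalue floor and repaired by QR (the deficient subspace is completed
   deterministically). Gross collapse — more than half the rows — raises.
2. **Labeling.** The first constrained pass starts from PVAF labels (next
   section). Afterwards each iteration re-labels from the opposite-block
   energy fraction `ρ` of the post-update mixing columns, with hysteresis:
   a shared component is promoted when `ρ < θ` (smallest fractions first,
   caps respected), a specific one demoted only when `ρ > 0.45`, near the
   ~0.5 equilibrium of genuinely shared components. Without the gap the
   label oscillates whenever `ρ` hovers at `θ` and the fixed point never
   settles. The first 10 constrained iterations keep the PVAF labels
   unchanged (the first post-projection updates are transient), and
   convergence cannot be declared before this burn-in has passed. Labels
   freeze over the last 10% of the iteration budget.
3. **Constraint enforcement.** Each specific row is orthogonally projected
   onto its feasible subspace (a row annihilated by the projection is
   demoted); rows within a group are symmetrically orthonormalized, which
   preserves feasibility because the subspace is closed under linear
   combinations; orthogonality *across* the two specific sets is restored
   by least-norm feasible Newton sweeps — each pairwise correction moves a
   row only inside its own subspace. A final symmetric orthogonalization
   guarantees `W` is exactly orthonormal at every iteration; whatever
   cross-correlation the sweeps could not remove becomes a small
   feasibility residual.

At convergence the residual `ρ` of every specific component is checked
against `constraint_tol` (default `1e-4`): the worst offender is demoted to
shared and the constraint re-enforced, repeatedly, so the specific count
shrinks — possibly to zero — rather than the whole set being discarded when
one component makes the joint constraints unsatisfiable. Components are
finally ordered by the energy of their back-projected mixing columns
(explained group-data variance) and signed so every spatial map has
positive skewness.

With `max_specific = (0, 0)` the whole constrained phase is skipped and the
result is exactly the plain symmetric FastICA fit — the group-ICA baseline
(`fit_gica_baseline`), which is also available on a two-level reduction
(subject PCA, identity group level, aggregate whitening).

### Initial labeling by PVAF

Component power is compared across subjects via the percent variance
accounted for: `PVAF = (1 − var(Y − Ŷ_c)/var(Y)) × 100`, with `Ŷ_c` the
single-component back-reconstruction and `var` the average over time points
of the across-voxel variance. A pooled two-sample t-test compares the two
groups' PVAF values per component; a component is a specific candidate at
Bonferroni significance `0.05/N` on the side with the larger mean, and
candidates beyond the caps are dropped keeping the lowest p-values.

### The classification threshold θ

A perfectly specific component still shows a nonzero opposite-block
fraction: the sample spatial correlation between its map and the opposite
group's retained directions contributes roughly `Ng / D` where `D` is the
number of spatial degrees of freedom (resels) in a map. At full fMRI scale
(`M ≈ 28 000`, `D ≈ 10³–10⁴`) this floor is ~0.03 and the default
`θ = 0.1` separates cleanly. On the package's desk-scale grid
(`M ≈ 700`, `D ≈ 10²`) the floor is ~0.1, so the bundled experiments run at
`θ = 0.25` — still far below the ~0.35–0.5 fractions of genuinely shared or
strongly partial components. θ is a first-class configuration parameter and
is swept over [0, 1] in the ROC protocol.

## Back-reconstruction and group statistics

The chain is linear, so subject `i`'s mixing matrix is
`M_ij = B_ij D_j A`, where `D_j` is the group-`j` row block of `G⁺` and
`B_ij` the subject-`i` row block of `H_j⁺`. Subject maps are the
least-squares solution `pinv(M_ij) X_ij` against the level-1-reduced data;
subject time courses live in the original time domain via `F_ij⁺`. The
single-component reconstruction `Ŷ_c = F_ij⁺ B_ij D_j A_c S` (all other
columns zeroed) is rank one and feeds PVAF; summing it over components
reproduces the full reconstruction to machine precision (linearity).

Group maps use voxel-wise t statistics: one-sample (`df = n − 1`) for
shared components, pooled two-sample (`df = n1 + n2 − 2`) for specific
ones. Zero-variance voxels get `t = 0` with a warning rather than ±inf.
The conventional report threshold `t = 3.17` is carried as a configuration
default only. Network strength is quantified by regressing each time
point's data on a network map (one least-squares coefficient per time
point) and integrating the Hamming-windowed periodogram of that time course
over 0–0.25 Hz (the Nyquist band at TR = 2 s).

## The hybrid-data simulator

The simulator emulates the statistical structure of "hybrid" validation
data — real resting-state background plus planted focal activations — with
a fully synthetic, seeded background:

* **Subject-unique noise**: Gaussian fields smoothed spatially (FWHM 1.5
  voxels, matching 6 mm smoothing at 4 mm resolution) and AR(1)-correlated
  in time (coefficient 0.3, a typical fMRI value), normalized to unit mean
  voxel variance.
* **Shared network modes**: a fixed set (default 6) of smooth seeded maps,
  common to every subject, each driven per subject and run by an
  independent 0.01–0.1 Hz band-limited unit-variance time course, each
  carrying 10% of the brain's spatial energy. These stand in for the
  resting-state networks all human brains share. They are not cosmetic:
  the aggregate-level eigenvalues are `1 ± σ_i` with `σ_i` the cross-group
  spatial correlations, and without strongly shared structure (large σ) no
  direction of the aggregate data is preferentially shared or specific —
  the very contrast the method extracts. A background without shared modes
  makes the level-3 reduction blind to specificity.

Patches are 2–3 blobs with a radial amplitude gradient from 1.3 (centre)
to 0.7 (edge), rescaled so the support mean is exactly 1; default blob
radius is 1.6 voxels, keeping each patch at ~2.5% of the mask — the focal
blob-to-brain proportion of realistic planted activations. Patch *power* is
the variance of its time course relative to the mean background voxel
variance; time-course amplitude is scaled by √snr so the realized power
equals the configured `snr` exactly. Time courses are band-limited to
0.01–0.1 Hz per subject, patch and run. Specific patches contribute exactly
zero to the opposite group; partially-specific ones are scaled to power
`snr × power_ratio` there; the first-listed specific patch of each group is
scaled by the unbalance ratio `m`. Within-component variability `k` adds
independent Gaussian noise of variance `k ×` background variance to each
blob's time course before re-band-limiting. Anatomical noise `n` translates
each subject's patches by a uniform integer shift in
`{−⌊n/2⌋, …, ⌊n/2⌋}²` in the axial plane. Everything is reproducible
bit-for-bit from the design seed.

What the simulator does **not** emulate: hemodynamic response shapes,
physiological noise and scanner drift, non-Gaussian background amplitude
distributions, realistic network topographies, and registration errors
beyond rigid in-plane translation. Passing tests therefore demonstrate the
estimator's behaviour under the stated generative model, not performance on
any particular scanner's data.

## Evaluation

Maps are compared after Z-scoring over mask voxels and thresholding at
`|Z| > 2.3`; RMSE and squared Pearson correlation `r²` quantify agreement,
and truth-to-component assignment is greedy one-to-one by descending `r²`
(sign-blind, since ICA signs are arbitrary). The similarity ratio
`r1/√(r1² + r2²)` (strong vs weak patch correlations) and the splitting
factor `max_l mean(Z_l,weak)/(mean(Z_l,weak) + mean(Z_l,strong))` over
blobs `l` diagnose under- and over-capacity regimes; blob means are taken
on the jitter-free truth supports, and negative means are floored at zero.
The shared/specific ROC treats shared as the positive class and the optimal
operating point minimizes `fpr² + fnr²`; the group-ICA comparison arm
classifies a component as specific when its back-reconstructed two-sample
difference map has at least a threshold count of voxels significant at α
(0.01 or 0.001). Reliability clustering of repeated runs is average-linkage
agglomerative clustering on pairwise spatial correlation, cut at a
similarity threshold, with voxel-wise mean representatives re-Z-scored.

## Desk-scale experiment designs

All bundled experiments use a 16×16×8 grid with an inscribed ellipsoidal
mask (~700 voxels), 6 subjects × 2 runs of T = 100 (TR 2 s) per group,
patches at SNR 1 and 6 shared background networks; fits run at most 60
iterations of each phase with θ = 0.25. Reduction dimensions
`(subject, Ng1, Ng2, N)` and specific caps per experiment:

| experiment | dims | caps | patches |
|---|---|---|---|
| recovery | (20, 8, 8, 10) | (2, 2) | 1 specific/group + 1 shared |
| under-capacity | (20, 9, 9, 11) | (1, 1) | 2 specific/group + 1 shared, unbalance m |
| over-capacity | (20, 10, 10, 14) | (2, 2) | 1 specific/group (radius 2.5) + 2 shared, variability k |
| partial | (20, 8, 8, 11) | (1, 1) | 1 partial/group + 1 shared |

`Ng` is chosen to retain each group's strong directions (networks + its
patches); `N` leaves the feasible subspaces `N − Ng` strictly larger than
the caps (see the corollary above). Two designs deserve comment:

* **Over-capacity** uses larger blobs because splitting requires the
  within-patch *difference* direction — energy
  `≈ (1 − blob-tc correlation) × blob energy` — to survive the group-level
  PCA noise floor; radius-1.6 blobs fall below it.
* **Partial specificity** uses `Ng = 8`: a partial component classifies as
  specific precisely when the *opposite* group's PCA drops its direction,
  whose eigenvalue is ≈ background baseline + `power_ratio ×` patch
  eigenvalue. With the retention cut inside the strong cluster the
  crossover lands between power ratios 0.5 and 0.9, reproducing the
  characteristic shape of the classification-rate curve (specific below
  ~0.5, shared above). With a lower cut (`Ng = 9`) every partial direction
  is retained and everything classifies shared.

These problem sizes — 10 seeds for recovery and spectral experiments, 20
seeds (40 specific components) for the capacity and partial experiments —
are the package's chosen defaults for its validation suite and are what
`scripts/acceptance.py` re-runs.

## Numerical choices and degenerate inputs

* Rank-deficient subject data: retain `min(requested, numerical rank at
  1e-10 relative tolerance)` dimensions with a logged warning; group and
  aggregate whitening refuse dimensions beyond the matrix rank.
* Classification ties (both groups' fractions below θ): smaller fraction
  wins; exact tie → shared. `θ = 0` labels everything shared.
* The random seed controls the initial unmixing matrix (QR of a seeded
  Gaussian matrix with a fixed sign convention).
* Zero-variance data rejects PVAF; zero network maps reject the spatial
  regression; bands beyond Nyquist reject the power computation.
* Non-convergence returns a result with `converged=False` and full
  diagnostics; near-Gaussian surplus components commonly keep rotating
  below the convergence tolerance without affecting the structured
  components.

## Known limitations

* Two groups only; the block formulation generalizes but is not
  implemented for more.
* The constraint is enforced by exact projection; the equilibrium between
  independence maximization and feasibility is reached by alternation, and
  convergence of the alternation is not formally guaranteed (in practice
  the structured components settle within tens of iterations).
* Desk-scale geometry compresses spatial degrees of freedom ~30-fold
  relative to whole-brain data; thresholds that depend on sample spatial
  correlations (θ, the classification floor) scale accordingly and should
  be revisited for real data.
* The simulator's background realism limits are listed above.
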