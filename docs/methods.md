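# Methods

## Model

The single-simulation LIE estimate for compound c from simulation i is

ΔG_i = α·ΔV_vdw,i + β·ΔV_el,i

with ΔV_x,i = ⟨V_x⟩_bound,i − ⟨V_x⟩_free the bound-minus-free difference of
ensemble-average ligand–surrounding interaction energies (kJ mol⁻¹). The
model is strictly two-parameter: no intercept term is included, and α, β
are unconstrained in sign (a warning is logged when a fitted coefficient is
negative, since negative coefficients usually indicate a pathological fit).

N independent simulations of one complex are combined with Boltzmann
weights W_i = softmax(−ΔG_i / k_B·T) and ΔG_calc = Σ W_i·ΔG_i. The weights
use k_B = 0.0083145 kJ mol⁻¹ K⁻¹ and the simulation temperature
(default 300 K, the production-MD temperature). The combination is computed
in shifted log space (scipy's softmax), so energy gaps of arbitrary size
neither overflow nor underflow; the result is always inside
[min ΔG_i, max ΔG_i], and adding a constant to every ΔG_i leaves the
weights unchanged.

**Replicates are not Boltzmann states.** Runs that differ only in the
random initial velocities sample the same free energy basin, so they are
merged first — an n_frames-weighted mean of the replicate averages (plain
mean when frame counts are absent) — and N counts (template × pose)
combinations only. With two protein templates, three poses each and two
replicates, twelve bound simulations collapse to N = 6 states.

## Calibration

With weights fixed, ΔG_calc is linear in (α, β) through the per-compound
weighted sums (ΣW_i·ΔV_vdw,i, ΣW_i·ΔV_el,i), so the least-squares fit
against ΔG_exp is an exact 2-column linear solve. Because the weights
depend on (α, β), calibration iterates a fixed-point loop:

1. initialize every compound's weights uniform;
2. solve the weighted least-squares problem for (α, β);
3. recompute all weights at the new parameters (optionally damped:
   w ← λ·w_new + (1−λ)·w_old, default λ = 1);
4. stop when max|Δα|, |Δβ| and the largest single-weight change all fall
   below `tol` (default 1e−8), or flag `converged=False` at
   `max_iterations` (default 1000).

The damping factor exists because plain fixed-point iteration can
oscillate when pose estimates are nearly degenerate; it is configuration,
not a default behavior change. The design matrix is rank-checked each
iteration: if the electrostatic differences are collinear with the van der
Waals differences across the training set, α and β are not separately
identifiable and calibration raises a degeneracy error instead of returning
an arbitrary solution. On data constructed to satisfy the model exactly,
the loop converges to the generating (α, β) to better than 1e−6 (verified
in the test suite), since the truth is a fixed point with zero residuals.

Prediction at a calibrated model is non-iterative: per-simulation
estimates, weights, combination — one pass.

## Error metrics

RMSE (training set) and SDEP (test set) share one formula,
sqrt(mean((ΔG_calc − ΔG_exp)²)) over the stated subset; no mean-bias
subtraction and no n−1 correction are applied. This makes the identity
RMSE_tot²·n = RMSE_train²·n_train + SDEP_test²·n_test hold exactly, which
the permutation scan exploits as a consistency check.

## Affinity conversion

ΔG_exp = R·T·ln(Ki/1 M) with Ki = IC50/(1 + [S]/Km). The 1 M standard
state makes the logarithm's argument dimensionless; R is numerically
k_B·N_A = 0.0083145 kJ mol⁻¹ K⁻¹, shared with the weighting code. The
packaged 17-compound fixture uses [S] = 1.5 μM and Km = 0.5 μM, so
Ki = IC50/4. The assay temperature defaults to 310 K: a one-parameter
brute-force fit of T over 270–320 K against all 17 tabulated
(IC50, ΔG_exp) pairs identifies 310 K as the unique value reproducing the
tabulated free energies to the printed precision — consistent with a
physiological-temperature assay. One tabulated pair (training ligand 8,
IC50 = 0.28 μM vs ΔG_exp = −42.56 kJ mol⁻¹) is internally inconsistent by
0.10 kJ mol⁻¹ at any temperature that fits the other sixteen; the fixture
stores both values verbatim and the corresponding regression test
documents the discrepancy by failing.

## Pose clustering

Pairwise pose RMSDs are computed over heavy atoms **without**
superposition: poses docked into one rigid template share a coordinate
frame, and translational differences between binding positions are signal,
not noise. A Kabsch-superposition flag exists for other uses. Hydrogens
are excluded by default because docking protonation is unreliable.

Clustering is the greedy nearest-neighbor scheme: repeatedly seed on the
pose with the most unassigned neighbors within the RMSD cutoff (ties to
the lowest pose index), emit seed+neighbors as a cluster, remove them.
Populations are non-increasing by construction and membership partitions
the retained poses, so results are deterministic given the matrix. The
emitted-cluster cap (default 5) is a cap at a user-supplied cutoff
(default 0.2 nm), not a cutoff search — the cutoff is a tunable because no
universal value exists across ligand sizes. Each cluster's central
structure is the member with the smallest mean RMSD to the others
(singletons are their own center; ties to the lowest index).

Clusters whose central structure's geometric center lies farther than
`site_radius` from `site_center` (both user-supplied, nm; e.g. a
heme-iron-derived center and a docking-sphere radius of 1.0–2.5 nm) are
discarded with a logged distance; the criterion is qualitative in origin,
so both numbers are configuration rather than constants. The ≤3 most
populated surviving clusters' central structures become MD starting poses,
tagged I/II/III by population rank. An empty selection is a warning, not
an error, because downstream models can proceed with fewer states.

## Permutation scan and applicability domain

The scan enumerates all C(n, k) train/test partitions in lexicographic
order (deterministic, seedless), refits (α, β) per partition on its
training side only, predicts all n compounds, and records RMSE_train,
SDEP_test and RMSE_tot per split, streaming rows to CSV when requested so
the 24,310-split case for n = 17, k = 9 runs in bounded memory
(~2 minutes on one core). Non-converged calibrations are recorded, not
dropped.

The applicability check embeds each compound at its weighted, scaled
coordinates (α·ΣW_i·ΔV_vdw,i, β·ΣW_i·ΔV_el,i). The training compounds
define a centroid and a 2×2 covariance (ddof = 1); eigen-decomposition
gives the principal axes. A query's per-axis score is its absolute
centered projection divided by the axis spread, and it is flagged when any
score exceeds the multiplier (default 2). "Spread" defaults to the
standard deviation sqrt(λ_k) — the conventional Mahalanobis-per-axis
normalization, in which the two scores combine in quadrature to the full
Mahalanobis distance — with `spread="variance"` selectable for the literal
two-times-the-variance reading; the ambiguity is surfaced as configuration
rather than resolved silently. The check requires ≥3 training compounds
and raises on a singular covariance. This analysis deliberately uses
simulation-derived coordinates only: it must be computable for compounds
with no experimental affinity.

## Synthetic data generator

The generator emulates the statistical structure of the study's inputs:
per compound, a free-state energy pair, a base (ΔV_vdw, ΔV_el) drawn
around (−100 ± 20, −30 ± 15) kJ mol⁻¹ — so at (α*, β*) = (0.22, 0.10) true
ΔG values land in the −48…−27 kJ mol⁻¹ affinity window of the fixture
compounds — and per-simulation perturbations split across both channels so
the single-simulation estimates spread by `pose_dg_spread` (default
7.5 kJ mol⁻¹ ≈ 3 k_B·T at 300 K, enough that weighting is decidedly
non-uniform). Replicate averages add Gaussian noise of
`replicate_noise_sigma` (default 1 kJ mol⁻¹); ΔG_exp adds
`experimental_noise_sigma` (default 2 kJ mol⁻¹, the order of experimental
reproducibility for IC50-derived free energies). Defaults mirror the study
layout: 17 compounds (9 train), 2 templates × 3 poses × 2 replicates.
All draws come from one seeded `numpy` generator.

What the generator does **not** emulate: MD time-series autocorrelation
and convergence error, force-field systematic error, pose-selection
failure (it never produces a "wrong pose" whose energies violate the
linear model), or any correlation between a compound's identity and its
energies. Passing tests therefore demonstrate the estimator's
correctness and statistical behavior under model-consistent data — not
that LIE assumptions hold for any real protein.

The pose-cloud generator places Gaussian blobs of rigid jittered atom
skeletons `separation` nm apart, giving clustering tests a known
ground-truth partition.

## Numerical choices and problem sizes

- Weights via scipy `softmax` (shift-stable); normalization holds to
  ≤1e−12 by construction and is asserted property-style.
- Least squares via `numpy.linalg.lstsq`; rank checked explicitly to turn
  silent minimum-norm solutions into loud degeneracy errors.
- All tie-breaks (cluster seeds, central structures) go to the lowest
  index; simulation keys order lexicographically by (template, pose), so
  every pipeline stage is deterministic given its inputs.
- CSV round trips use `%.17g` on write and round-trip float parsing on
  read, so datasets survive write/read bit-identically.
- Test-suite simulation sizes (6–17 compounds, scans of C(6,3) splits,
  pose clouds of ≤300 poses) are chosen to exercise every code path while
  keeping the default suite around a few seconds; the full 24,310-split
  scan is exercised through the enumeration layer plus small-n scans, and
  end-to-end via the CLI example.

## Known limitations

- The fixed-point calibration has no global-convergence guarantee; for
  adversarial data it may oscillate (mitigated by damping) or converge to
  a local fixed point. Diagnostics (`converged`, `n_iterations`,
  per-iteration debug logging) expose this rather than hiding it.
- The applicability domain is a two-dimensional ellipsoid criterion on
  weighted energies; it flags extrapolation in energy space only and
  cannot detect chemistry outside the training domain that happens to land
  inside the ellipse.
- The clustering cutoff and active-site radius are study-dependent
  configuration with no universally correct defaults.
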