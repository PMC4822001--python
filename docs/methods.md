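# Methods

This note documents the models and estimators implemented in conformakin,
the defaults they ship with, what the synthetic-data generators do and do
not emulate, and the numerical choices made where the design was open.

## Featurization

A conformation is a vector of minimum heavy-atom distances (Å) over all
residue pairs with sequence separation j − i ≥ `min_separation`
(default 3, read literally as an index difference; ≥ 4 is available for
the stricter "three residues between" reading). Heavy atoms are
identified by element ≠ H. Named pair distances support `min_heavy`
(consistent with the contact map) and `c_alpha` modes. Dihedrals use the
right-handed IUPAC sign convention (cis = 0, trans = ±π) via the
cross-product atan2 formulation; the test suite cross-checks it against
an independent Gram–Schmidt projection formulation. Subset RMSD uses the
least-squares superposition with the proper-rotation (det = +1)
constraint.

The partial-unfolding classifier marks a conformation partially unfolded
when the Met124–Ala128 inter-Cα distance exceeds 11 Å **or** the
Ala128–Gly134 distance exceeds 15 Å. The two cutoffs monitor distinct
local-unfolding modes (helix-G unwinding and deformation of the second
Ca²⁺-binding site), so either deformation alone qualifies; an AND
combination is available (`combine="and"`) for sensitivity analysis, and
both cutoffs are configurable.

## tICA

The model solves C(Δt) v = λ C(0) v on mean-free data. Choices:

- The lagged covariance is symmetrized, (C(Δt) + C(Δt)ᵀ)/2, before
  solving, guaranteeing a real spectrum.
- Time-lagged pairs are drawn within trajectories only; multiple
  trajectories pool their covariance sums weighted by frame/pair counts.
- Rank deficiency is handled by ridge regularization of C(0) with
  ε = 10⁻⁶ · trace/d, which is deterministic and leaves well-conditioned
  problems essentially untouched (a constant feature then receives ~0
  weight in retained components rather than producing a spurious unit
  eigenvalue).
- Eigenvector sign is fixed by making the largest-magnitude loading
  positive, so loadings plots and regression tests are stable.
- The lag is specified in frames; `TICA.from_time_lag` converts a Δt in
  ns through the frame spacing (default trajectory spacing 0.1 ns),
  warning when rounding is needed. The pipeline default Δt is 40 ns with
  20 retained components, the settings used for the calmodulin C-lobe
  analysis.

## Clustering

Microstates: greedy farthest-point k-centers (2-approximation to the
optimal covering radius). The first center is frame 0 unless a seed is
given, in which case it is drawn uniformly; both choices are
deterministic and reproducible. Duplicate points that reduce the
effective number of centers are allowed and logged. The pipeline default
is 100 microstates.

Macrostates: agglomerative clustering on a pairwise subset-RMSD (or any
symmetric dissimilarity) matrix, cut at n = 5 by default. Average
linkage is the default — robust for RMSD-like matrices whose clusters
are irregular — with complete linkage available. Because the matrix is
O(n²), macrostating a long MSM trajectory should operate on a subsample
(≈2000 frames) with remaining frames assigned to the nearest
representative; the representative of a cluster is the member with
minimal mean dissimilarity to the others.

## Markov state model

Transition counts use a sliding window (every origin t with t + τ in
range), maximising data use. The count graph is trimmed to its largest
strongly connected component before estimation, since the reversible
estimator needs connectivity; size ties break toward the component with
more counts. The transition matrix is the detailed-balance-constrained
maximum-likelihood estimate via the standard self-consistent iteration
on symmetric auxiliary variables, converged at max relative change
< 10⁻¹⁰ (hard cap 10⁶ iterations); naive symmetrization (C + Cᵀ)/2 is
available behind `reversible=False` for comparison. Implied timescales
are −τ/ln μ; eigenvalues within 10⁻¹² of 1 map to +inf, and nonpositive
or complex eigenvalues are reported as NaN with a warning.

Markovian lag selection: implied timescales are tabulated over a lag
list, and the suggested lag is the smallest whose slowest timescale
changes by < 10% relative to each of the next two tested lags. This is a
concrete reading of "convergence behaviour" and is configurable; it is a
suggestion, not an automatism.

Free-energy landscapes: P(x, y) = Σ_i π_i h_i(x, y) with h_i the
normalized histogram of each microstate's frames, F = −kT ln P shifted
to min 0, empty bins NaN. Default 100 bins per axis over the observed
data range; kT defaults to 0.5924 kcal/mol (298 K, the simulation
temperature of the source study). Normalizing h_i per state means a
state's weight is its equilibrium probability regardless of how many
frames sampled it — the reweighting that corrects adaptive-sampling
bias.

Adaptive-sampling seeds are the n least-populated states (ties by state
index), mirroring the seeding of new sampling rounds from low-π states.

## Transition path theory

Forward committors solve the interior linear system with q = 0 on the
source set and 1 on the sink set; backward committors use the
time-reversed chain (equal to 1 − q⁺ under detailed balance, which the
tests verify). Net flux is max(f_ij − f_ji, 0) of the gross reactive
flux. Pathways are decomposed by iterative widest-path (max–min
bottleneck) subtraction with ties broken toward the lexicographically
smallest state sequence, so the decomposition is deterministic; the
default stops at 90% of the total flux because exhaustive decomposition
is exponential. The flux fraction through an intermediate set is the
decomposed-pathway flux touching the set over the total decomposed flux.
To connect state-level classification (e.g. partial unfolding) with
frame-level rules, classify a state by the majority vote of its frames.

## Kinetic Monte Carlo and observables

KMC trajectories draw the next state from the current row of T(τ); steps
are one lag time apart with no sub-lag interpolation, and the default
start is the most populated state. Observable series draw one
conformation uniformly from the visited state's pool per step.
Equilibrium frame weights for ensemble averages are
w(frame) = π(state)/n_frames(state).

S² uses the isotropic second-rank formula
S² = (3[⟨x²⟩² + ⟨y²⟩² + ⟨z²⟩² + 2⟨xy⟩² + 2⟨xz⟩² + 2⟨yz⟩²] − 1)/2 on unit
bond vectors; it is rotation-invariant and clipped to [0, 1] only
against floating-point overshoot.

Torsion mutual information uses a 24 × 24 histogram with equal-occupancy
(quantile) bin edges per marginal — the adaptive partitioning used by
torsion-MI methods, which keeps discretization bias small for sharply
peaked rotamer distributions (fixed-width bins on (−π, π] are available
but underestimate MI badly for concentrated angles). The shuffle-null
correction subtracts the mean MI of 20 independent permutations of one
series and floors at 0, removing the positive finite-sample bias; MI is
reported in nats so the bivariate-Gaussian closed form −½ ln(1 − ρ²)
serves as an exact oracle. Residue-level coupling aggregates torsion
pairs by max (default) or sum.

## Structures

PDB files are read with gemmi; alternate locations resolve to the
highest-occupancy conformer and the first model of multi-model files is
used unless selected otherwise. Extraction refuses chains covering less
than 80% of E82–A147 rather than inventing coordinates — completing
missing residues is the user's job with a loop-modelling tool.
Projection of a structure into a fitted tIC space requires its contact
map to match the model's pair labels exactly.

## Synthetic data: what it does and does not emulate

The generators replace hundreds of microseconds of all-atom MD with
analytically controllable processes, trading realism for exact ground
truth:

- `sample_markov_chain` — exact discrete jump statistics for a known
  row-stochastic matrix.
- `brownian_dynamics` — overdamped Euler–Maruyama on quartic double
  wells, stationary density ∝ exp(−βU); no inertia, thermostat or
  solvent detail. dt must keep the drift step finite (the integrator
  reports the step index otherwise).
- `toy_polymer` — 12-bead chain alternating between a hard-coded
  extended and hairpin geometry (inter-reference RMSD ≈ 13 Å) under
  symmetric Markov switching plus isotropic Gaussian noise; exercises
  featurization, clustering and the MSM end to end.
- `correlated_torsions` — wrapped bivariate Gaussians with σ = 0.3 rad,
  chosen so wrapping perturbs the closed-form MI by ≪ 10⁻⁶ nat.
- `cone_vectors` — uniform on a spherical cap, with the
  diffusion-in-a-cone closed form S² = [cos θ₀(1 + cos θ₀)/2]².

Every generator is a pure function of its arguments including the seed
(default 42). Passing tests on these fixtures demonstrates estimator
correctness — not that real MD data satisfies the Markovian,
stationarity or sampling assumptions; on real data, lag-scan convergence
and Chapman–Kolmogorov checks remain the user's responsibility.

## Problem sizes and tolerances in the validation suite

Statistical assertions are stated in standard errors wherever the
quantity admits one (binomial SEs for transition frequencies, SEs from
basin-switch counts for occupation fractions), with sample sizes chosen
so those intervals are decisively small: 10⁶ steps for chain and KMC
statistics, 10⁶ samples for the closed-form observables, 10⁷ Brownian
steps for the Boltzmann-histogram check (KL < 0.01 over 50 bins), and
10⁵ frames for the end-to-end polymer recovery (~2000 hidden switches).
Exact algebraic identities (implied-timescale closed form, committor
systems, flux conservation, projection arithmetic) are asserted at
10⁻⁸–10⁻¹² absolute. Brute-force oracles (exhaustive k-subset search,
simple-path enumeration, set partitions, rotation-grid RMSD refinement)
run on ≤ 20-point instances where enumeration is exact.

## Known limitations

- No Bayesian MSM uncertainties, hidden Markov models, or spectral
  coarse-graining (PCCA); macrostates come from geometric clustering.
- No kinetic-map or kernel tICA variants.
- The reversible MLE requires every active state to have outgoing
  counts; heavily fragmented data should be trimmed or re-lagged first.
- The MI estimator is histogram-based; k-NN estimators are out of scope.
- Trajectory I/O covers the native array container and PDB; compressed
  MD formats (DCD/XTC) can be converted through mdtraj upstream.
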