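# conformakin

Markov state model (MSM) analysis of protein conformational exchange, built
around the workflow used to characterise the microsecond dynamics of the
calmodulin C-lobe (C-CaM, residues E82–A147): the ligand-free (apo) domain
transiently visits a holo-like state that presents the hydrophobic binding
interface, so target binding can proceed by conformational selection.
The package is for computational biophysicists who have (or simulate)
trajectory data and want the full kinetic-model stack with every stage
testable against analytic ground truth.

## What it computes

Each conformation is represented as a vector |X⟩ of minimum heavy-atom
distances between residue pairs separated by at least three residues (the
contact map). Time-structure-based independent component analysis (tICA)
solves the generalized eigenproblem

    C(Δt) v = λ C(0) v

on mean-free features, where C(0) is the instantaneous and C(Δt) the
symmetrized time-lagged covariance; the N slowest eigenvectors form the
d × N projection matrix P, and distances between conformations are
d(A, B) = ‖Pᵀ|A⟩ − Pᵀ|B⟩‖₂. The projected space is discretized with greedy
k-centers clustering; a reversible (detailed-balance-constrained)
maximum-likelihood transition matrix T(τ) is estimated from sliding-window
transition counts; its leading left eigenvector is the equilibrium
distribution π and its eigenvalues μ give implied timescales t = −τ/ln μ.
On top of the MSM the package provides:

- **Transition path theory** — committors q⁺/q⁻, net reactive flux
  f_ij = π_i q⁻_i T_ij q⁺_j, widest-path pathway decomposition, and flux
  fractions through intermediate state sets (e.g. partially unfolded
  states classified by the Met124–Ala128 > 11 Å / Ala128–Gly134 > 15 Å
  inter-Cα cutoffs).
- **Kinetic Monte Carlo** — trajectories sampled from the rows of T(τ) with
  per-frame observables realised from per-state conformation pools.
- **Free-energy landscapes** — F(x, y) = −kT ln Σ_i π_i h_i(x, y) with
  per-state normalized histograms h_i and kT = 0.5924 kcal/mol (298 K).
- **Observables** — NMR generalized order parameters S² from weighted bond
  vector ensembles, torsion mutual information (nats) with a shuffle-null
  bias correction, and Pearson correlation against experimental tables.
- **Structures** — extraction of the E82–A147 block from PDB files and
  projection of published complex structures into a fitted tIC space.
- **Synthetic data** — Markov chains, Brownian dynamics on double wells,
  a two-state bead polymer, correlated torsion pairs and cone-distributed
  bond vectors, all with closed-form ground truth.

The API follows the statsmodels convention: `TICA(...)` and
`MarkovStateModel(...)` are model objects whose `fit()` returns results
objects (`TICAResults`, `MSMResults`) carrying estimates, spectra,
diagnostics and `summary()`; TPT, sampling and landscapes hang off
`MSMResults`.

## Worked example

Blind recovery of hidden two-state kinetics through the full pipeline
(contact features → tICA → k-centers → two macrostates → reversible MSM)
on the switching bead polymer:

```python
from conformakin.pipeline import two_state_blind_recovery

out = two_state_blind_recovery(n_frames=100_000, switch_prob=0.02,
                               noise_sigma=0.3, seed=42)
print(out["recovered_T01"])          # 0.0206
print(out["recovered_populations"])  # [0.4853 0.5147]
print(out["assignment_accuracy"])    # 1.0
```

The generating chain switches states with probability 0.02 per frame; the
pipeline, seeing only noisy coordinates, recovers 0.0206, an even
population split within sampling error (~2000 observed switches), and a
frame assignment that matches the hidden labels exactly. The model
objects print their own diagnostics:

```python
from conformakin import synthetic, contact_features, TICA

traj, _ = synthetic.toy_polymer(20_000, switch_prob=0.02, seed=42)
feats = contact_features(traj, min_separation=3)
print(TICA(feats, lag=5, n_components=3).fit().summary())
```

```
tICA results
========================================
features (d):        45
components (N):      3
lag (frames):        5
eigenvalues:         0.8183, 0.0577, 0.0532
```

The single large eigenvalue is the slow inter-state hop; the near-zero
rest are measurement noise. A `conformakin` command-line interface wraps
the same stages (`conformakin synth | featurize | tica | msm | tpt |
sample | run`); `conformakin run` drives the whole chain from a YAML
config and writes a checksummed artifact manifest.

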