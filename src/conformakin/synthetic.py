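"""Ground-truth-labelled synthetic inputs for pipeline validation.

Every generator here is a pure function of its arguments, including the
seed, so reruns are bit-identical.  The generators supply the statistical
structure the analysis stack assumes — discrete Markov jump dynamics,
diffusion on multi-well potentials with a Boltzmann stationary density, a
two-state bead polymer for end-to-end featurization tests, correlated
torsion pairs with a closed-form mutual information, and bond vectors
uniform on a spherical cap with a closed-form order parameter.
"""

from __future__ import annotations

import logging
import math
from bisect import bisect_right
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .trajectory import Topology, Trajectory

logger = logging.getLogger(__name__)

DEFAULT_SEED = 42

__all__ = [
    "SyntheticGroundTruth",
    "validate_transition_matrix",
    "stationary_distribution",
    "sample_markov_chain",
    "DoubleWell1D",
    "SeparableDoubleWell2D",
    "brownian_dynamics",
    "toy_polymer",
    "open_reference",
    "compact_reference",
    "correlated_torsions",
    "correlated_torsions_mi",
    "cone_vectors",
    "cone_s2",
]


@dataclass
class SyntheticGroundTruth:
    """What a generator promised to produce, for downstream recovery tests."""

    kind: str
    parameters: dict = field(default_factory=dict)
    seed: int = DEFAULT_SEED
    true_labels: Optional[np.ndarray] = None


def validate_transition_matrix(T: np.ndarray, tol: float = 1e-10) -> np.ndarray:
    T = np.asarray(T, dtype=float)
    if T.ndim != 2 or T.shape[0] != T.shape[1]:
        raise ValueError(f"transition matrix must be square, got shape {T.shape}")
    if np.any(T < 0):
        i = int(np.argwhere(T < 0)[0][0])
        raise ValueError(f"transition matrix row {i} has a negative entry")
    rowsums = T.sum(axis=1)
    bad = np.nonzero(np.abs(rowsums - 1.0) > tol)[0]
    if len(bad):
        raise ValueError(
            f"transition matrix row {int(bad[0])} sums to {rowsums[bad[0]]!r}, not 1"
        )
    return T


def stationary_distribution(T: np.ndarray) -> np.ndarray:
    """Stationary distribution of an irreducible row-stochastic matrix.

    Computed as the leading left eigenvector, normalised to sum 1.
    Raises on reducible chains (stationary vector not unique).
    """
    from scipy.sparse.csgraph import connected_components

    T = validate_transition_matrix(T)
    n_comp, _ = connected_components(T > 0, directed=True, connection="strong")
    if n_comp > 1:
        raise ValueError("chain is reducible; stationary distribution is not unique")
    vals, vecs = np.linalg.eig(T.T)
    k = int(np.argmin(np.abs(vals - 1.0)))
    pi = np.real(vecs[:, k])
    pi = np.abs(pi)
    return pi / pi.sum()


def sample_markov_chain(T, n_steps: int, start="stationary", seed: int = DEFAULT_SEED) -> np.ndarray:
    """Sample a discrete trajectory from a row-stochastic transition matrix.

    ``start`` is a state index, or ``"stationary"`` to draw the initial
    state from the stationary distribution (requires an irreducible chain).
    """
    T = validate_transition_matrix(T)
    n = T.shape[0]
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    rng = np.random.default_rng(seed)
    if isinstance(start, str):
        if start != "stationary":
            raise ValueError(f"unknown start rule {start!r}")
        pi = stationary_distribution(T)
        state = int(rng.choice(n, p=pi))
    else:
        state = int(start)
        if not 0 <= state < n:
            raise ValueError(f"start state {state} outside [0, {n})")
    # cumulative rows as plain lists: bisect is ~3x faster than np.searchsorted
    # in a scalar loop
    cum = [np.cumsum(T[i])[:-1].tolist() for i in range(n)]
    u = rng.random(n_steps - 1)
    out = np.empty(n_steps, dtype=np.int64)
    out[0] = state
    for t in range(1, n_steps):
        state = bisect_right(cum[state], u[t - 1])
        out[t] = state
    return out


class DoubleWell1D:
    """Symmetric quartic double well, βU(x) = h (x² − 1)²."""

    def __init__(self, h: float):
        self.h = float(h)

    def beta_u(self, x):
        return self.h * (np.asarray(x) ** 2 - 1.0) ** 2

    def grad_beta_u(self, x):
        return 4.0 * self.h * x * (x * x - 1.0)

    ndim = 1


class SeparableDoubleWell2D:
    """βU(x, y) = h₁ (x² − 1)² + h₂ (y² − 1)² (independent double wells)."""

    def __init__(self, h1: float, h2: float):
        self.h1 = float(h1)
        self.h2 = float(h2)

    def beta_u(self, xy):
        xy = np.asarray(xy)
        return (self.h1 * (xy[..., 0] ** 2 - 1.0) ** 2
                + self.h2 * (xy[..., 1] ** 2 - 1.0) ** 2)

    def grad_beta_u(self, xy):
        x, y = xy[..., 0], xy[..., 1]
        return np.stack([4.0 * self.h1 * x * (x * x - 1.0),
                         4.0 * self.h2 * y * (y * y - 1.0)], axis=-1)

    ndim = 2


def brownian_dynamics(potential, beta: float = 1.0, diffusion: float = 1.0,
                      dt: float = 1e-3, n_steps: int = 100_000,
                      seed: int = DEFAULT_SEED, x0=None) -> np.ndarray:
    """Overdamped Euler–Maruyama path on a 1D or 2D potential.

    The update is x ← x − D Δt ∇(βU)(x) + √(2 D Δt) ξ with standard normal
    ξ, which has stationary density ∝ exp(−βU) for small Δt.  ``beta``
    rescales the supplied reduced potential (βU is stored at β = 1).
    Returns shape ``(n_steps,)`` for 1D potentials, ``(n_steps, 2)`` for 2D.
    """
    if dt <= 0 or diffusion <= 0:
        raise ValueError("dt and diffusion must be positive")
    rng = np.random.default_rng(seed)
    sig = math.sqrt(2.0 * diffusion * dt)
    a = diffusion * dt * beta

    if potential.ndim == 1:
        x = 1.0 if x0 is None else float(x0)
        noise = rng.normal(0.0, sig, size=n_steps)
        out = np.empty(n_steps)
        g = potential.grad_beta_u
        h = getattr(potential, "h", None)
        if h is not None:
            # unrolled quartic gradient: pure-float loop, no array overhead
            c = 4.0 * h * a
            for t in range(n_steps):
                x = x - c * x * (x * x - 1.0) + noise[t]
                out[t] = x
        else:
            for t in range(n_steps):
                x = x - a * g(x) + noise[t]
                out[t] = x
        if not math.isfinite(out[-1]) or not np.all(np.isfinite(out)):
            bad = int(np.nonzero(~np.isfinite(out))[0][0])
            raise FloatingPointError(
                f"non-finite coordinate at step {bad}: time step too large")
        return out

    if potential.ndim == 2:
        if x0 is None:
            x, y = 1.0, 1.0
        else:
            x, y = float(x0[0]), float(x0[1])
        noise = rng.normal(0.0, sig, size=(n_steps, 2))
        out = np.empty((n_steps, 2))
        c1 = 4.0 * potential.h1 * a
        c2 = 4.0 * potential.h2 * a
        for t in range(n_steps):
            x = x - c1 * x * (x * x - 1.0) + noise[t, 0]
            y = y - c2 * y * (y * y - 1.0) + noise[t, 1]
            out[t, 0] = x
            out[t, 1] = y
        if not np.all(np.isfinite(out)):
            bad = int(np.nonzero(~np.isfinite(out).all(axis=1))[0][0])
            raise FloatingPointError(
                f"non-finite coordinate at step {bad}: time step too large")
        return out

    raise ValueError("potential must be 1D or 2D")


# ---------------------------------------------------------------------------
# Toy bead polymer with two metastable geometries
# ---------------------------------------------------------------------------

_N_BEADS = 12
_BOND = 3.8  # Å, Cα–Cα virtual bond


def open_reference() -> np.ndarray:
    """Extended 12-bead chain: beads on a straight line, 3.8 Å apart."""
    coords = np.zeros((_N_BEADS, 3))
    coords[:, 0] = _BOND * np.arange(_N_BEADS)
    return coords


def compact_reference() -> np.ndarray:
    """Hairpin 12-bead chain: two antiparallel strands 5 Å apart."""
    coords = np.zeros((_N_BEADS, 3))
    half = _N_BEADS // 2
    coords[:half, 0] = _BOND * np.arange(half)
    coords[half:, 0] = _BOND * np.arange(half)[::-1]
    coords[half:, 1] = 5.0
    return coords


def _polymer_topology() -> Topology:
    names = np.array(["CA"] * _N_BEADS, dtype=object)
    elements = np.array(["C"] * _N_BEADS, dtype=object)
    resids = np.arange(1, _N_BEADS + 1)
    resnames = np.array(["ALA"] * _N_BEADS, dtype=object)
    return Topology(names, elements, resids, resnames)


def toy_polymer(n_frames: int, switch_prob: float = 0.02, noise_sigma: float = 0.3,
                seed: int = DEFAULT_SEED, frame_spacing: float = 0.1):
    """Two-state bead polymer: hidden symmetric Markov switching + Gaussian noise.

    Each frame is one of two hard-coded 12-bead reference geometries
    ("open" and "compact") plus isotropic Gaussian noise of scale
    ``noise_sigma`` (Å).  The hidden state follows a symmetric two-state
    chain with per-frame switch probability ``switch_prob``.

    Returns ``(Trajectory, labels)`` where ``labels[t] ∈ {0 (open), 1 (compact)}``.
    """
    if not 0 < switch_prob < 1:
        raise ValueError("switch_prob must be in (0, 1)")
    refs = np.stack([open_reference(), compact_reference()])
    # separability warning: compare rigid-alignment RMSD of references to noise
    diff = refs[0] - refs[0].mean(0) - (refs[1] - refs[1].mean(0))
    inter_rmsd = math.sqrt((diff ** 2).sum() / _N_BEADS)
    if noise_sigma > 0 and inter_rmsd < 2.0 * noise_sigma:
        logger.warning(
            "toy_polymer: reference RMSD %.2f Å < 2*noise_sigma %.2f Å; "
            "states may not be separable", inter_rmsd, 2 * noise_sigma)

    T = np.array([[1 - switch_prob, switch_prob], [switch_prob, 1 - switch_prob]])
    labels = sample_markov_chain(T, n_frames, start="stationary", seed=seed)
    rng = np.random.default_rng((seed, 1))
    coords = refs[labels] + rng.normal(0.0, noise_sigma, size=(n_frames, _N_BEADS, 3))
    traj = Trajectory(coords, _polymer_topology(), frame_spacing)
    return traj, labels


def correlated_torsions(rho: float, n: int, seed: int = DEFAULT_SEED,
                        sigma: float = 0.3) -> tuple[np.ndarray, np.ndarray]:
    """Paired torsion series (radians) with known mutual information.

    Pairs are bivariate Gaussian with correlation ``rho`` and marginal
    standard deviation ``sigma`` (default 0.3 rad), wrapped to (−π, π].
    With σ = 0.3 the wrapping perturbs the Gaussian closed-form MI,
    −½ ln(1−ρ²), by far less than sampling error.
    """
    if not -1.0 <= rho <= 1.0:
        raise ValueError("rho must lie in [-1, 1]")
    rng = np.random.default_rng(seed)
    z1 = rng.normal(size=n)
    if abs(rho) == 1.0:
        z2 = math.copysign(1.0, rho) * z1
    else:
        z2 = rho * z1 + math.sqrt(1.0 - rho * rho) * rng.normal(size=n)
    a = sigma * z1
    b = sigma * z2
    wrap = lambda x: np.mod(x + np.pi, 2 * np.pi) - np.pi
    return wrap(a), wrap(b)


def correlated_torsions_mi(rho: float) -> float:
    """Closed-form MI (nats) of the generating bivariate Gaussian."""
    return -0.5 * math.log(1.0 - rho * rho)


def cone_vectors(theta0: float, n: int, seed: int = DEFAULT_SEED) -> np.ndarray:
    """Unit vectors uniform on the spherical cap of semi-angle ``theta0`` about +z."""
    if not 0.0 <= theta0 <= math.pi:
        raise ValueError("theta0 must lie in [0, pi]")
    rng = np.random.default_rng(seed)
    # uniform area element: cos(theta) uniform on [cos(theta0), 1]
    c = rng.uniform(math.cos(theta0), 1.0, size=n)
    s = np.sqrt(np.clip(1.0 - c * c, 0.0, None))
    phi = rng.uniform(0.0, 2 * math.pi, size=n)
    return np.column_stack([s * np.cos(phi), s * np.sin(phi), c])


def cone_s2(theta0: float) -> float:
    """Diffusion-in-a-cone order parameter, S² = [cosθ₀(1+cosθ₀)/2]²."""
    c = math.cos(theta0)
    return (c * (1.0 + c) / 2.0) ** 2
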