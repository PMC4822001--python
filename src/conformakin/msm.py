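"""Markov state model estimation.

Transitions are counted with a sliding window at lag τ; the count graph is
trimmed to its largest strongly connected component; the transition matrix
T(τ) is the reversible (detailed-balance-constrained) maximum-likelihood
estimate obtained by the standard self-consistent iteration.  The leading
left eigenvector of T(τ) is the equilibrium distribution π; the remaining
eigenvalues μ give the implied timescales of the dynamic processes,

    t_i = −τ / ln μ_i .

Conformational free-energy landscapes follow from the reweighted
histogram  P(x, y) = Σ_i π_i h_i(x, y),  F = −kT ln P, where h_i is the
normalized histogram of the order parameters restricted to microstate i.

Organisation follows statsmodels: :class:`MarkovStateModel` holds the
discrete trajectories and lag, ``fit()`` returns :class:`MSMResults` with
the estimates, spectra, diagnostics and the simulation/TPT entry points.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.sparse.csgraph import connected_components

logger = logging.getLogger(__name__)

# kT in kcal/mol at the 298 K simulation temperature
KT_298K = 0.5924

__all__ = ["CountMatrix", "count_transitions", "MarkovStateModel", "MSMResults",
           "implied_timescales", "lag_scan", "FreeEnergyGrid",
           "free_energy_surface", "adaptive_seed_states", "KT_298K"]


@dataclass
class CountMatrix:
    """Observed transition counts n_ij at a fixed lag."""

    counts: np.ndarray
    lag: int                  # frames
    total_frames: int
    frame_spacing: float = 1.0  # ns per frame

    @property
    def lag_time(self) -> float:
        """Lag in ns."""
        return self.lag * self.frame_spacing

    @property
    def n_states(self) -> int:
        return self.counts.shape[0]


def count_transitions(dtrajs, lag: int, n_states: Optional[int] = None,
                      frame_spacing: float = 1.0) -> CountMatrix:
    """Sliding-window transition counts at integer lag (frames).

    Every time origin t with t+lag in range contributes one pair; pairs
    never cross trajectory boundaries.
    """
    if isinstance(dtrajs, np.ndarray) and dtrajs.ndim == 1:
        dtrajs = [dtrajs]
    dtrajs = [np.asarray(d, dtype=np.int64) for d in dtrajs]
    if lag < 1:
        raise ValueError("lag must be >= 1 frame")
    usable = [d for d in dtrajs if len(d) > lag]
    if not usable:
        raise ValueError(f"no trajectory longer than the lag ({lag} frames)")
    if n_states is None:
        n_states = int(max(d.max() for d in dtrajs)) + 1
    counts = np.zeros((n_states, n_states))
    for d in usable:
        np.add.at(counts, (d[:-lag], d[lag:]), 1.0)
    total = sum(len(d) for d in dtrajs)
    return CountMatrix(counts=counts, lag=lag, total_frames=total,
                       frame_spacing=frame_spacing)


def _largest_connected_set(counts: np.ndarray) -> np.ndarray:
    """Largest strongly connected component of the count graph.

    Size ties are broken toward the component with the most counts, then
    the smallest member index.
    """
    n_comp, labels = connected_components(counts > 0, directed=True,
                                          connection="strong")
    best = None
    for c in range(n_comp):
        members = np.nonzero(labels == c)[0]
        total = counts[np.ix_(members, members)].sum()
        key = (len(members), total, -int(members[0]))
        if best is None or key > best[0]:
            best = (key, members)
    return best[1]


def _reversible_mle(counts: np.ndarray, tol: float = 1e-10,
                    max_iter: int = 1_000_000) -> tuple[np.ndarray, np.ndarray]:
    """Detailed-balance-constrained multinomial MLE of T.

    Self-consistent fixed-point on the symmetric auxiliary variables
    x_ij:  x_ij ← (c_ij + c_ji) / (c_i/x_i + c_j/x_j),  with x_i = Σ_j x_ij
    and c_i the observed row sums.  Converged when the max relative change
    of x falls below ``tol``.  Returns (T, π).
    """
    c = np.asarray(counts, dtype=float)
    csym = c + c.T
    ci = c.sum(axis=1)
    if np.any(ci == 0):
        raise ValueError("reversible MLE requires at least one outgoing count per state")
    x = csym.copy()
    x_rows = x.sum(axis=1)
    for it in range(max_iter):
        q = ci / x_rows
        denom = q[:, None] + q[None, :]
        x_new = np.where(csym > 0, csym / denom, 0.0)
        new_rows = x_new.sum(axis=1)
        delta = np.max(np.abs(x_new - x) / np.maximum(np.abs(x), 1e-300))
        x, x_rows = x_new, new_rows
        if delta < tol:
            break
    else:
        raise RuntimeError(f"reversible MLE did not converge; residual {delta:.3e}")
    pi = x_rows / x_rows.sum()
    T = x / x_rows[:, None]
    return T, pi


class MarkovStateModel:
    """MSM estimator over discrete trajectories at a fixed lag.

    Parameters
    ----------
    dtrajs : int array or list of int arrays
        Discrete state trajectories (e.g. from k-centers assignments).
    lag : int
        Lag time in frames.
    frame_spacing : float
        ns per frame; sets the unit of lag_time and implied timescales.
    reversible : bool
        Detailed-balance MLE (default).  ``False`` uses the naive
        symmetrization (C + Cᵀ)/2 before row-normalising, for comparison.
    """

    def __init__(self, dtrajs, lag: int, frame_spacing: float = 1.0,
                 reversible: bool = True):
        if isinstance(dtrajs, CountMatrix):
            self.counts_full = dtrajs
        else:
            self.counts_full = count_transitions(dtrajs, lag,
                                                 frame_spacing=frame_spacing)
        self.lag = self.counts_full.lag
        self.frame_spacing = self.counts_full.frame_spacing
        self.reversible = reversible

    def fit(self) -> "MSMResults":
        counts = self.counts_full.counts
        if counts.sum() == 0:
            raise ValueError("count matrix contains no transitions")
        active = _largest_connected_set(counts)
        sub = counts[np.ix_(active, active)]
        if len(active) == 1:
            T = np.array([[1.0]])
            pi = np.array([1.0])
        elif self.reversible:
            T, pi = _reversible_mle(sub)
        else:
            s = 0.5 * (sub + sub.T)
            T = s / s.sum(axis=1, keepdims=True)
            pi = s.sum(axis=1) / s.sum()
        vals = np.linalg.eigvals(T)
        order = np.argsort(-np.abs(vals))
        vals = vals[order]
        eigenvalues = np.where(np.abs(vals.imag) < 1e-12, vals.real, np.nan)
        if np.any(np.isnan(eigenvalues)):
            logger.warning("complex eigenvalues present (non-reversible estimate)")
        return MSMResults(T=T, pi=pi, eigenvalues=eigenvalues,
                          lag=self.lag, frame_spacing=self.frame_spacing,
                          active_set=active, counts=self.counts_full,
                          model=self)


@dataclass
class MSMResults:
    """Estimated Markov state model.

    ``T`` and ``pi`` are indexed over the active set (states surviving the
    ergodic trim); ``active_set`` maps those indices back to the original
    state labels.
    """

    T: np.ndarray
    pi: np.ndarray
    eigenvalues: np.ndarray
    lag: int
    frame_spacing: float
    active_set: np.ndarray
    counts: Optional[CountMatrix] = field(default=None, repr=False)
    model: Optional[MarkovStateModel] = field(default=None, repr=False)

    def __post_init__(self) -> None:
        rows = self.T.sum(axis=1)
        if np.max(np.abs(rows - 1.0)) > 1e-10:
            raise ValueError("transition matrix rows must sum to 1")

    @property
    def n_states(self) -> int:
        return self.T.shape[0]

    @property
    def lag_time(self) -> float:
        """Lag in ns."""
        return self.lag * self.frame_spacing

    def timescales(self, k: Optional[int] = None) -> np.ndarray:
        """Implied timescales −τ/ln μ (ns), slowest first; μ₁ = 1 excluded."""
        ts = implied_timescales(self.eigenvalues, self.lag_time)
        return ts if k is None else ts[:k]

    def detailed_balance_residual(self) -> float:
        """Max relative violation of π_i T_ij = π_j T_ji."""
        flux = self.pi[:, None] * self.T
        denom = np.maximum(np.abs(flux), 1e-300)
        mask = (self.T > 0) | (self.T.T > 0)
        rel = np.abs(flux - flux.T) / denom
        return float(rel[mask].max()) if mask.any() else 0.0

    def map_to_active(self, states) -> np.ndarray:
        """Translate original state labels to active-set indices (−1 if trimmed)."""
        lookup = -np.ones(int(self.active_set.max()) + 1, dtype=np.int64)
        lookup[self.active_set] = np.arange(len(self.active_set))
        s = np.asarray(states, dtype=np.int64)
        return lookup[s]

    # -- downstream analyses ----------------------------------------------
    def tpt(self, source, sink):
        """Transition path theory between two state sets (active-set indices)."""
        from .tpt import transition_path_analysis
        return transition_path_analysis(self, source, sink)

    def sample(self, n_steps: int, start="most_populated", seed: int = 42):
        """Kinetic Monte Carlo trajectory from T (see :mod:`conformakin.sampling`)."""
        from .sampling import sample_msm_trajectory
        return sample_msm_trajectory(self, n_steps, start_rule=start, seed=seed)

    def free_energy_surface(self, observables, assignments, bins=100,
                            kT: float = KT_298K) -> "FreeEnergyGrid":
        return free_energy_surface(self, observables, assignments, bins=bins, kT=kT)

    def adaptive_seed_states(self, n: int) -> np.ndarray:
        return adaptive_seed_states(self.pi, n)

    def summary(self) -> str:
        ts = self.timescales(3)
        lines = [
            "Markov state model",
            "=" * 44,
            f"states (active / total): {self.n_states} / "
            f"{self.counts.n_states if self.counts else self.n_states}",
            f"lag:                     {self.lag} frames = {self.lag_time:g} ns",
            f"stationary entropy:      "
            f"{-(self.pi * np.log(np.maximum(self.pi, 1e-300))).sum():.3f} nats",
            f"top populations:         "
            + ", ".join(f"{p:.3f}" for p in np.sort(self.pi)[::-1][:5]),
            f"slowest timescales (ns): "
            + ", ".join("n/a" if np.isnan(t) else ("inf" if np.isinf(t) else f"{t:.3g}")
                        for t in ts),
            f"detailed-balance resid.: {self.detailed_balance_residual():.2e}",
        ]
        return "\n".join(lines)

    # -- serialization -----------------------------------------------------
    def save(self, path) -> None:
        meta = {"lag": self.lag, "frame_spacing": self.frame_spacing}
        np.savez(path, T=self.T, pi=self.pi, eigenvalues=self.eigenvalues,
                 active_set=self.active_set, _meta=json.dumps(meta))

    @classmethod
    def load(cls, path) -> "MSMResults":
        with np.load(path, allow_pickle=False) as z:
            meta = json.loads(str(z["_meta"]))
            return cls(T=z["T"], pi=z["pi"], eigenvalues=z["eigenvalues"],
                       lag=int(meta["lag"]), frame_spacing=float(meta["frame_spacing"]),
                       active_set=z["active_set"])


def implied_timescales(eigenvalues, lag_time: float) -> np.ndarray:
    """−τ/ln μ for each eigenvalue after the stationary μ₁ = 1.

    μ ≥ 1 − 1e-12 maps to +inf; nonpositive or complex (NaN-marked)
    eigenvalues are undefined and returned as NaN with a warning.
    """
    mu = np.asarray(eigenvalues, dtype=float)[1:]
    out = np.empty(len(mu))
    for i, m in enumerate(mu):
        if np.isnan(m) or m <= 0:
            out[i] = np.nan
        elif m >= 1.0 - 1e-12:
            out[i] = np.inf
        else:
            out[i] = -lag_time / np.log(m)
    if np.any(np.isnan(out)):
        warnings.warn("negative or complex eigenvalues: timescales undefined (NaN)")
    return out


def lag_scan(dtrajs, lags: Sequence[int], frame_spacing: float = 1.0,
             n_timescales: int = 3, rel_tol: float = 0.10):
    """Implied timescales versus lag, plus a suggested Markovian lag.

    The suggested lag is the smallest tested lag whose slowest implied
    timescale changes by less than ``rel_tol`` (default 10%) relative to
    each of the next two tested lags — a concrete convergence-behaviour
    rule.  Failed lags are skipped with a warning.

    Returns ``(table, suggested_lag)`` where table maps lag (frames) to
    the slowest ``n_timescales`` implied timescales (ns).
    """
    lags = sorted(int(l) for l in lags)
    if len(lags) < 3:
        raise ValueError("lag_scan needs at least 3 lags")
    table = {}
    for lag in lags:
        try:
            res = MarkovStateModel(dtrajs, lag, frame_spacing=frame_spacing).fit()
            table[lag] = res.timescales(n_timescales)
        except (ValueError, RuntimeError) as err:
            logger.warning("lag %d failed: %s", lag, err)
    ok = [l for l in lags if l in table and np.isfinite(table[l][0])]
    suggested = None
    for i, lag in enumerate(ok[:-2]):
        t0 = table[lag][0]
        if all(abs(table[ok[i + j]][0] - t0) / t0 < rel_tol for j in (1, 2)):
            suggested = lag
            break
    return table, suggested


@dataclass
class FreeEnergyGrid:
    """Free-energy landscape on a 2D (or 1D) order-parameter grid."""

    x_edges: np.ndarray
    y_edges: Optional[np.ndarray]
    F: np.ndarray                 # kcal/mol, NaN on empty bins, min = 0
    kT: float
    probability: np.ndarray       # P(x, y) = Σ_i π_i h_i

    def to_dataframe(self):
        import pandas as pd

        xc = 0.5 * (self.x_edges[:-1] + self.x_edges[1:])
        if self.y_edges is None:
            return pd.DataFrame({"x": xc, "F": self.F})
        yc = 0.5 * (self.y_edges[:-1] + self.y_edges[1:])
        xx, yy = np.meshgrid(xc, yc, indexing="ij")
        return pd.DataFrame({"x": xx.ravel(), "y": yy.ravel(), "F": self.F.ravel()})

    def plot(self, ax=None, **kwargs):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        if self.y_edges is None:
            xc = 0.5 * (self.x_edges[:-1] + self.x_edges[1:])
            ax.plot(xc, self.F, **kwargs)
            ax.set_ylabel("F (kcal/mol)")
        else:
            pc = ax.pcolormesh(self.x_edges, self.y_edges, self.F.T, **kwargs)
            ax.figure.colorbar(pc, ax=ax, label="F (kcal/mol)")
        return ax


def free_energy_surface(results: MSMResults, observables, assignments,
                        bins=100, kT: float = KT_298K) -> FreeEnergyGrid:
    """MSM-reweighted free-energy landscape over one or two order parameters.

    ``observables`` is (n_frames,) for 1D or (n_frames, 2) for 2D;
    ``assignments`` gives each frame's active-set state index.  Each
    state's histogram is normalized before weighting by π, so states are
    represented by their equilibrium probability regardless of how many
    frames sampled them.
    """
    obs = np.asarray(observables, dtype=float)
    assign = np.asarray(assignments, dtype=np.int64)
    if obs.shape[0] != len(assign):
        raise ValueError("observables and assignments must align per frame")
    two_d = obs.ndim == 2
    missing = np.setdiff1d(np.arange(results.n_states), np.unique(assign))
    if len(missing):
        raise ValueError(f"active state {int(missing[0])} has no observable frames")

    if two_d:
        if np.isscalar(bins):
            bins = (bins, bins)
        x_edges = np.histogram_bin_edges(obs[:, 0], bins[0])
        y_edges = np.histogram_bin_edges(obs[:, 1], bins[1])
        P = np.zeros((len(x_edges) - 1, len(y_edges) - 1))
        for i in range(results.n_states):
            sel = assign == i
            h, _, _ = np.histogram2d(obs[sel, 0], obs[sel, 1],
                                     bins=[x_edges, y_edges])
            P += results.pi[i] * h / h.sum()
    else:
        x_edges = np.histogram_bin_edges(obs, bins)
        y_edges = None
        P = np.zeros(len(x_edges) - 1)
        for i in range(results.n_states):
            h, _ = np.histogram(obs[assign == i], bins=x_edges)
            P += results.pi[i] * h / h.sum()

    with np.errstate(divide="ignore"):
        F = np.where(P > 0, -kT * np.log(np.maximum(P, 1e-300)), np.nan)
    F -= np.nanmin(F)
    return FreeEnergyGrid(x_edges=x_edges, y_edges=y_edges, F=F, kT=kT,
                          probability=P)


def adaptive_seed_states(pi: np.ndarray, n: int) -> np.ndarray:
    """The n states with smallest equilibrium probability (adaptive-sampling seeds).

    Ties are broken by ascending state index.  Mirrors seeding new
    sampling rounds from the least-populated states.
    """
    pi = np.asarray(pi, dtype=float)
    if n > len(pi):
        raise ValueError(f"n={n} exceeds number of states {len(pi)}")
    order = np.lexsort((np.arange(len(pi)), pi))
    return order[:n]
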