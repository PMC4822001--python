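"""Kinetic Monte Carlo sampling of an estimated Markov state model.

An MSM trajectory is generated by repeated multinomial draws from the
rows of T(τ): in state i at time t, the state at t + τ is drawn from
T_i.  Observable time series are realised by drawing, for each step, a
random conformation from the pool of frames belonging to the visited
state and evaluating the observable on it — the route from a discrete
kinetic model back to experiment-facing time traces.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass

import numpy as np

__all__ = ["MSMTrajectory", "sample_msm_trajectory", "realize_observables"]


@dataclass
class MSMTrajectory:
    """A KMC state sequence; consecutive entries are one lag time apart."""

    states: np.ndarray
    lag_time: float          # ns between steps
    seed: int

    @property
    def n_steps(self) -> int:
        return len(self.states)

    @property
    def times(self) -> np.ndarray:
        """Timestamps in ns (multiples of the lag)."""
        return np.arange(self.n_steps) * self.lag_time

    def __len__(self) -> int:
        return self.n_steps


def sample_msm_trajectory(results, n_steps: int, start_rule="most_populated",
                          seed: int = 42) -> MSMTrajectory:
    """Kinetic Monte Carlo trajectory from an MSM.

    ``start_rule`` is ``"most_populated"`` (argmax π, the default) or an
    explicit active-set state index.  Reproducible given the seed.
    """
    T = np.asarray(results.T, dtype=float)
    n = T.shape[0]
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    if isinstance(start_rule, str):
        if start_rule != "most_populated":
            raise ValueError(f"unknown start rule {start_rule!r}")
        state = int(np.argmax(results.pi))
    else:
        state = int(start_rule)
        if not 0 <= state < n:
            raise ValueError(f"start state {state} outside the active set (n={n})")
    rng = np.random.default_rng(seed)
    cum = [np.cumsum(T[i])[:-1].tolist() for i in range(n)]
    u = rng.random(n_steps - 1)
    states = np.empty(n_steps, dtype=np.int64)
    states[0] = state
    for t in range(1, n_steps):
        state = bisect_right(cum[state], u[t - 1])
        states[t] = state
    return MSMTrajectory(states=states, lag_time=float(getattr(results, "lag_time", 1.0)),
                         seed=seed)


def realize_observables(traj: MSMTrajectory, state_pools, observable=None,
                        seed: int = 42) -> np.ndarray:
    """Realise a per-frame observable along a KMC state sequence.

    ``state_pools`` maps each state index to the values (or frames) that
    belong to it: a list/dict of 1D arrays of precomputed observable
    values, or of arbitrary frame objects if ``observable`` (a callable
    applied to the drawn frame) is given.  For each step one pool entry
    is drawn uniformly at random.
    """
    rng = np.random.default_rng(seed)
    visited = np.unique(traj.states)
    pools = {}
    for s in visited:
        try:
            pool = state_pools[int(s)]
        except (KeyError, IndexError):
            raise ValueError(f"no conformation pool for visited state {int(s)}")
        pool = np.asarray(pool) if observable is None else list(pool)
        if len(pool) == 0:
            raise ValueError(f"empty conformation pool for visited state {int(s)}")
        pools[int(s)] = pool

    out = np.empty(traj.n_steps, dtype=float)
    picks = {int(s): rng.integers(0, len(pools[int(s)]), size=int((traj.states == s).sum()))
             for s in visited}
    counters = {int(s): 0 for s in visited}
    for t, s in enumerate(traj.states):
        s = int(s)
        k = picks[s][counters[s]]
        counters[s] += 1
        val = pools[s][k]
        out[t] = observable(val) if observable is not None else val
    return out
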