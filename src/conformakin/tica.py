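"""Time-structure-based independent component analysis (tICA).

tICA finds the linear combinations of input features that decorrelate most
slowly, by solving the generalized symmetric eigenproblem

    C(Δt) v = λ C(0) v

on mean-free data, where C(0) is the instantaneous covariance and C(Δt)
the symmetrized time-lag covariance at lag Δt.  Eigenvalues approximate
the feature autocorrelations at the lag; the leading eigenvectors (tICs)
span the slow subspace used as the distance metric for clustering:
d(A, B) = ‖Pᵀ|A⟩ − Pᵀ|B⟩‖₂ with P the d × N matrix of the N slowest tICs.

The model/result split follows the statsmodels convention: :class:`TICA`
holds the data and estimation settings, ``fit()`` returns a
:class:`TICAResults` carrying the spectrum, the projection matrix and the
derived operations (projection, tIC distance, loadings).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import scipy.linalg

from .features import ContactFeatures

logger = logging.getLogger(__name__)

__all__ = ["TICA", "TICAResults", "fit_tica"]


def _as_arrays(features) -> tuple[list[np.ndarray], Optional[list]]:
    """Normalise input to a list of (n_frames, d) arrays + optional pair labels."""
    pair_labels = None
    if isinstance(features, ContactFeatures):
        return [features.values], features.pair_labels
    if isinstance(features, np.ndarray):
        return [np.atleast_2d(np.asarray(features, dtype=float))], None
    arrays = []
    for f in features:
        if isinstance(f, ContactFeatures):
            if pair_labels is None:
                pair_labels = f.pair_labels
            arrays.append(f.values)
        else:
            arrays.append(np.atleast_2d(np.asarray(f, dtype=float)))
    return arrays, pair_labels


class TICA:
    """tICA model over one or more feature trajectories.

    Parameters
    ----------
    features : array, ContactFeatures, or list of either
        One (n_frames, d) feature trajectory per entry.  Time-lagged pairs
        are drawn within trajectories only, never across boundaries.
    lag : int
        Lag Δt in frames.  Use :meth:`from_time_lag` to specify in ns.
    n_components : int
        Number of slow components N to retain (default 20).
    regularization : float
        Ridge added to C(0) as ε·(trace/d)·I to handle rank deficiency.
    """

    def __init__(self, features, lag: int, n_components: int = 20,
                 regularization: float = 1e-6):
        self.trajectories, self.pair_labels = _as_arrays(features)
        d = self.trajectories[0].shape[1]
        for a in self.trajectories:
            if a.shape[1] != d:
                raise ValueError("all trajectories must share the feature dimension")
        self.d = d
        self.lag = int(lag)
        if self.lag < 1:
            raise ValueError("lag must be >= 1 frame")
        if n_components > d:
            raise ValueError(f"n_components {n_components} exceeds dimension {d}")
        self.n_components = int(n_components)
        self.regularization = float(regularization)

    @classmethod
    def from_time_lag(cls, features, delta_t: float, frame_spacing: float,
                      **kwargs) -> "TICA":
        """Build with the lag given in ns; rounds to the nearest frame."""
        frames = delta_t / frame_spacing
        lag = int(round(frames))
        if abs(frames - lag) > 1e-9:
            logger.warning("delta_t %.4g ns is %.4g frames; rounding lag to %d",
                           delta_t, frames, lag)
        return cls(features, lag=lag, **kwargs)

    def fit(self) -> "TICAResults":
        usable = [a for a in self.trajectories if a.shape[0] > self.lag]
        if not usable:
            raise ValueError(f"no trajectory longer than the lag ({self.lag} frames)")

        # pooled mean over all frames of usable trajectories
        n_total = sum(a.shape[0] for a in usable)
        mean = sum(a.sum(axis=0) for a in usable) / n_total

        c0 = np.zeros((self.d, self.d))
        ct = np.zeros((self.d, self.d))
        n0 = 0
        npair = 0
        for a in usable:
            x = a - mean
            c0 += x.T @ x
            n0 += x.shape[0]
            xt, xl = x[:-self.lag], x[self.lag:]
            ct += xt.T @ xl
            npair += xt.shape[0]
        c0 /= n0
        ct /= npair
        ct = 0.5 * (ct + ct.T)  # symmetrize: guarantees a real spectrum

        eps = self.regularization * np.trace(c0) / self.d
        c0_reg = c0 + eps * np.eye(self.d)

        vals, vecs = scipy.linalg.eigh(ct, c0_reg)
        order = np.argsort(vals)[::-1]
        vals = vals[order][: self.n_components]
        vecs = vecs[:, order][:, : self.n_components]
        # sign convention: largest-|loading| entry of each component positive
        for k in range(vecs.shape[1]):
            j = int(np.argmax(np.abs(vecs[:, k])))
            if vecs[j, k] < 0:
                vecs[:, k] = -vecs[:, k]

        return TICAResults(model=self, mean=mean, cov_instantaneous=c0,
                           cov_lagged=ct, components=vecs, eigenvalues=vals,
                           lag=self.lag, pair_labels=self.pair_labels)


@dataclass
class TICAResults:
    """Fitted tICA: slow subspace, spectrum and projection operations."""

    mean: np.ndarray
    cov_instantaneous: np.ndarray
    cov_lagged: np.ndarray
    components: np.ndarray        # d × N, columns normalised under C(0)
    eigenvalues: np.ndarray       # length N, descending
    lag: int                      # frames
    pair_labels: Optional[list] = None
    model: Optional[TICA] = field(default=None, repr=False)

    @property
    def n_components(self) -> int:
        return self.components.shape[1]

    def timescales(self, frame_spacing: float = 1.0) -> np.ndarray:
        """Relaxation timescales −Δt/ln λ (same unit as frame_spacing·lag)."""
        tau = self.lag * frame_spacing
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where((self.eigenvalues > 0) & (self.eigenvalues < 1),
                            -tau / np.log(self.eigenvalues), np.inf)

    def _check_dim(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if x.shape[-1] != self.mean.shape[0]:
            raise ValueError(
                f"feature dimension {x.shape[-1]} does not match model d={self.mean.shape[0]}")
        return x

    def project(self, X, n: Optional[int] = None) -> np.ndarray:
        """Pᵀ(X − mean) truncated to the first n components."""
        if isinstance(X, ContactFeatures):
            X = X.values
        x = self._check_dim(X)
        n = self.n_components if n is None else int(n)
        return (x - self.mean) @ self.components[:, :n]

    def tic_distance(self, A, B, n: Optional[int] = None) -> float:
        """Euclidean distance between projections of two conformations."""
        pa = self.project(np.atleast_1d(np.asarray(A, dtype=float)), n)
        pb = self.project(np.atleast_1d(np.asarray(B, dtype=float)), n)
        return float(np.linalg.norm(pa - pb))

    def top_loadings(self, component: int = 0, k: int = 25) -> list:
        """The k feature pairs with the largest |weight| in one component.

        Returns (label, signed weight) tuples, ranked by |weight|; labels
        are residue pairs when the model was fitted on contact features,
        else feature column indices.
        """
        if component >= self.n_components:
            raise IndexError(f"component {component} >= N={self.n_components}")
        w = self.components[:, component]
        if k > len(w):
            logger.warning("k=%d exceeds dimension %d; truncating", k, len(w))
            k = len(w)
        order = np.argsort(-np.abs(w))[:k]
        labels = self.pair_labels if self.pair_labels is not None else list(range(len(w)))
        return [(labels[i], float(w[i])) for i in order]

    def summary(self) -> str:
        lines = [
            "tICA results",
            "=" * 40,
            f"features (d):        {self.mean.shape[0]}",
            f"components (N):      {self.n_components}",
            f"lag (frames):        {self.lag}",
            "eigenvalues:         "
            + ", ".join(f"{v:.4f}" for v in self.eigenvalues[:5])
            + (" ..." if self.n_components > 5 else ""),
        ]
        return "\n".join(lines)

    # -- serialization -----------------------------------------------------
    def save(self, path) -> None:
        meta = {"lag": self.lag,
                "pair_labels": self.pair_labels if self.pair_labels is None
                else [list(map(int, p)) for p in self.pair_labels]}
        np.savez(path, mean=self.mean, cov_instantaneous=self.cov_instantaneous,
                 cov_lagged=self.cov_lagged, components=self.components,
                 eigenvalues=self.eigenvalues, _meta=json.dumps(meta))

    @classmethod
    def load(cls, path) -> "TICAResults":
        with np.load(path, allow_pickle=False) as z:
            meta = json.loads(str(z["_meta"]))
            pl = meta["pair_labels"]
            return cls(mean=z["mean"], cov_instantaneous=z["cov_instantaneous"],
                       cov_lagged=z["cov_lagged"], components=z["components"],
                       eigenvalues=z["eigenvalues"], lag=int(meta["lag"]),
                       pair_labels=None if pl is None else [tuple(p) for p in pl])


def fit_tica(features, lag: int, n_components: int = 20, **kwargs) -> TICAResults:
    """One-call convenience wrapper: ``TICA(features, lag, n_components).fit()``."""
    return TICA(features, lag=lag, n_components=n_components, **kwargs).fit()
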