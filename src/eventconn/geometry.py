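"""Inter-contact Euclidean distances and the exponential distance-decay model.

Contacts live in MNI space (millimetres, RAS).  Connectivity strength falls
off with distance roughly as s = A exp(-tau d): A is the hypothetical
strength at zero separation and tau (per mm) the decay rate — larger tau
means coupling dies out over shorter distances.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.spatial.distance import pdist, squareform

__all__ = ["DistanceMatrix", "DecayFit", "distance_matrix", "fit_decay"]

A_MAX = 1.5  # upper bound for the zero-distance strength of a [0,1] index


@dataclass
class DistanceMatrix:
    d: np.ndarray
    channel_labels: list[str]


@dataclass
class DecayFit:
    """Least-squares fit of s = A exp(-tau d)."""

    A: float
    tau: float
    rmse: float
    n_pairs: int


def distance_matrix(geometry: pd.DataFrame) -> DistanceMatrix:
    """Pairwise Euclidean distances (mm) from a table with label, x_mm, y_mm, z_mm."""
    if geometry["label"].duplicated().any():
        raise ValueError("duplicate channel labels")
    if len(geometry) < 2:
        raise ValueError("need at least 2 channels")
    coords = geometry[["x_mm", "y_mm", "z_mm"]].to_numpy(dtype=float)
    if not np.all(np.isfinite(coords)):
        raise ValueError("non-finite coordinates")
    return DistanceMatrix(
        d=squareform(pdist(coords)), channel_labels=list(geometry["label"])
    )


def fit_decay(h_values: np.ndarray, d_values: np.ndarray) -> DecayFit:
    """Fit s = A exp(-tau d) to per-pair strengths by nonlinear least squares.

    Pairs with a missing strength are dropped listwise.  The fit is
    unweighted, tau is constrained to be non-negative, and the optimizer is
    started from a log-domain linear fit over the strictly positive
    strengths.  The returned fit is never worse than the best constant model
    (A = mean, tau = 0).
    """
    h = np.asarray(h_values, dtype=float)
    d = np.asarray(d_values, dtype=float)
    ok = np.isfinite(h) & np.isfinite(d)
    h, d = h[ok], d[ok]
    if h.size < 5:
        raise ValueError("need at least 5 finite (h, d) pairs")
    if np.any(h < 0):
        raise ValueError("strengths must be non-negative")
    if not np.any(h > 0):
        raise ValueError("all strengths are zero")

    # log-domain initialization on the positive strengths
    pos = h > 0
    if pos.sum() >= 2 and np.ptp(d[pos]) > 0:
        slope, intercept = np.polyfit(d[pos], np.log(h[pos]), 1)
        tau0 = max(0.0, -slope)
        A0 = float(np.clip(np.exp(intercept), 1e-9, A_MAX))
    else:
        tau0, A0 = 0.0, float(np.clip(h.mean(), 1e-9, A_MAX))

    def resid(p):
        return p[0] * np.exp(-p[1] * d) - h

    sol = least_squares(
        resid, x0=[A0, min(tau0, 10.0)], bounds=([0.0, 0.0], [A_MAX, np.inf])
    )
    A_hat, tau_hat = sol.x
    sse = float(np.sum(resid(sol.x) ** 2))

    # guard: a constant model is in the parameter space (tau = 0)
    A_const = float(np.clip(h.mean(), 0.0, A_MAX))
    sse_const = float(np.sum((A_const - h) ** 2))
    if sse_const < sse:
        A_hat, tau_hat, sse = A_const, 0.0, sse_const

    return DecayFit(
        A=float(A_hat), tau=float(tau_hat),
        rmse=float(np.sqrt(sse / h.size)), n_pairs=int(h.size),
    )
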