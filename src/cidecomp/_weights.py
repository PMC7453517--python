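"""Weighted moments with the population (divide-by-total-weight) convention.

Survey weights here are frequency-style sampling weights; all moments divide
by the total weight rather than by (n - 1), so that identities such as
CI = 2 cov(h, r) / mu hold exactly rather than up to a finite-sample factor.
"""

from __future__ import annotations

import numpy as np


def as_weights(w, n: int) -> np.ndarray:
    """Validate a weight vector; ``None`` means equal weights."""
    if w is None:
        return np.ones(n, dtype=float)
    w = np.asarray(w, dtype=float)
    if w.shape != (n,):
        raise ValueError(f"weights have shape {w.shape}, expected ({n},)")
    if not np.all(np.isfinite(w)):
        raise ValueError("weights must be finite")
    if np.any(w <= 0):
        raise ValueError("weights must be strictly positive")
    return w


def wmean(x, w=None) -> float:
    x = np.asarray(x, dtype=float)
    w = as_weights(w, x.shape[0])
    return float(np.average(x, weights=w))


def wcov(x, y, w=None) -> float:
    """Weighted covariance, population convention."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    w = as_weights(w, x.shape[0])
    xm = np.average(x, weights=w)
    ym = np.average(y, weights=w)
    return float(np.average((x - xm) * (y - ym), weights=w))


def wvar(x, w=None) -> float:
    return wcov(x, x, w)
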