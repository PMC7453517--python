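"""Concentration indices for wealth-related inequality.

The concentration index (CI) of a variable ``x`` against the weighted
fractional wealth rank ``r`` is

    CI = 2 cov_w(x, r) / mu,        mu = weighted mean of x,

negative when the variable is concentrated among the poor. For a bounded
variable with bounds (a, b) — (0, 1) for a binary outcome — the Erreygers
normalization

    E = 4 mu CI / (b - a)

removes the prevalence-dependent bounds of the standard CI, which for a
binary variable can never exceed 1 - mu in magnitude.

The generalized concentration index GC(e) = 2 cov_w(e, r) of regression
residuals carries the unexplained part of a decomposition (GC_e / mu).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._weights import as_weights, wcov, wmean

__all__ = [
    "ConcentrationResult",
    "concentration_index",
    "erreygers_index",
    "generalized_concentration",
]


@dataclass(frozen=True)
class ConcentrationResult:
    """Standard and Erreygers-normalized concentration index of one variable."""

    ci: float
    erreygers: float
    mu: float
    bounds: tuple[float, float] | None

    def __iter__(self):  # allows ``ci, e, mu, bounds = result``
        return iter((self.ci, self.erreygers, self.mu, self.bounds))


def _infer_bounds(x: np.ndarray) -> tuple[float, float] | None:
    vals = np.unique(x)
    if np.isin(vals, (0.0, 1.0)).all():
        return (0.0, 1.0)
    return None


def concentration_index(x, rank, weights=None, bounds="auto") -> ConcentrationResult:
    """Weighted concentration index of ``x`` against fractional rank ``rank``.

    Parameters
    ----------
    x : array-like
        Variable of interest (outcome or determinant).
    rank : array-like
        Weighted fractional rank of the equity stratifier, built with the
        same weights (see :func:`cidecomp.wealth.fractional_rank`).
    weights : array-like, optional
        Strictly positive sampling weights; equal weights if omitted.
    bounds : tuple, None or "auto"
        Bounds (a, b) of the variable, used for the Erreygers index.
        ``"auto"`` takes (0, 1) for binary data and leaves the Erreygers
        index undefined (NaN) otherwise.

    Returns
    -------
    ConcentrationResult
        With ``ci``, ``erreygers`` (NaN when no bounds apply), ``mu``.
    """
    x = np.asarray(x, dtype=float)
    rank = np.asarray(rank, dtype=float)
    if x.shape != rank.shape:
        raise ValueError("x and rank must have the same length")
    if x.size == 0:
        raise ValueError("empty input")
    w = as_weights(weights, x.shape[0])
    mu = wmean(x, w)
    if mu == 0.0:
        raise ZeroDivisionError("concentration index undefined: weighted mean is 0")
    ci = 2.0 * wcov(x, rank, w) / mu
    if bounds == "auto":
        bounds = _infer_bounds(x)
    res = ConcentrationResult(ci=ci, erreygers=np.nan, mu=mu, bounds=bounds)
    if bounds is not None:
        res = ConcentrationResult(ci=ci, erreygers=erreygers_index(res), mu=mu, bounds=bounds)
    return res


def erreygers_index(result: ConcentrationResult) -> float:
    """Erreygers-normalized index 4 mu CI / (b - a) of a bounded variable."""
    if result.bounds is None:
        raise ValueError("Erreygers index requires variable bounds (a, b)")
    a, b = result.bounds
    if not b > a:
        raise ValueError(f"invalid bounds: need b > a, got ({a}, {b})")
    return 4.0 * result.mu * result.ci / (b - a)


def generalized_concentration(e, rank, weights=None) -> float:
    """Generalized concentration index 2 cov_w(e, rank); no mean scaling."""
    e = np.asarray(e, dtype=float)
    rank = np.asarray(rank, dtype=float)
    if e.shape != rank.shape:
        raise ValueError("e and rank must have the same length")
    w = as_weights(weights, e.shape[0])
    return 2.0 * wcov(e, rank, w)
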