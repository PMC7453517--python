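"""Asset-based wealth index, quintiles and weighted fractional ranks.

The wealth index is the first principal component of household asset
indicators — the standard DHS-style proxy for household economic status.
Indicators are standardized and projected onto the leading eigenvector of
their (weighted) correlation matrix; the score's sign is oriented so that
higher means richer. The weighted fractional rank of the score is the
equity stratifier ``r`` entering every concentration index.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from ._weights import as_weights

__all__ = ["WealthIndex", "WealthRanking", "fractional_rank", "wealth_quintiles", "rank_households"]


@dataclass(frozen=True)
class WealthRanking:
    """Per-row wealth score, quintile (1 = poorest) and fractional rank."""

    score: np.ndarray
    quintile: np.ndarray
    rank: np.ndarray
    weights: np.ndarray


class WealthIndex(BaseEstimator, TransformerMixin):
    """First-principal-component wealth score from asset indicators.

    Parameters
    ----------
    weighted : bool, default True
        Use the sampling-weighted correlation matrix of the indicators;
        with ``False`` the ordinary correlation matrix is used.
    orient_by : str, int or None, default None
        Column (name for DataFrame input, position otherwise) designating a
        "richer" indicator; the score is sign-flipped if needed so that it
        correlates positively with that column. With ``None`` the score is
        oriented to correlate positively with the total asset count per
        household (owning more assets = richer).
    drop_constant : bool, default True
        Drop zero-variance indicator columns with a warning instead of
        failing; at least two informative columns must remain.

    Attributes
    ----------
    loadings_ : ndarray of shape (n_kept,)
        First-eigenvector loadings on the standardized kept indicators.
    mean_, scale_ : ndarray
        Weighted means / standard deviations used for standardization.
    columns_ : list
        Names (or positions) of the kept indicator columns.
    dropped_ : list
        Constant columns removed during fitting.
    explained_variance_ratio_ : float
        Share of total indicator variance carried by the first component.
    """

    def __init__(self, weighted: bool = True, orient_by=None, drop_constant: bool = True):
        self.weighted = weighted
        self.orient_by = orient_by
        self.drop_constant = drop_constant

    @staticmethod
    def _to_frame(X) -> pd.DataFrame:
        if isinstance(X, pd.DataFrame):
            return X
        return pd.DataFrame(np.asarray(X, dtype=float))

    def fit(self, X, y=None, sample_weight=None):
        F = self._to_frame(X)
        A = F.to_numpy(dtype=float)
        n, k = A.shape
        if n == 0:
            raise ValueError("empty asset matrix")
        w = as_weights(sample_weight, n) if self.weighted else np.ones(n)
        mean = np.average(A, axis=0, weights=w)
        var = np.average((A - mean) ** 2, axis=0, weights=w)
        keep = var > 0
        self.dropped_ = [c for c, k_ in zip(F.columns, keep) if not k_]
        if self.dropped_:
            if not self.drop_constant:
                raise ValueError(f"constant asset columns: {self.dropped_}")
            warnings.warn(f"dropping constant asset columns: {self.dropped_}", UserWarning)
        if keep.sum() < 2:
            raise ValueError("need at least two asset columns with nonzero variance")
        self.columns_ = [c for c, k_ in zip(F.columns, keep) if k_]
        self.mean_ = mean[keep]
        self.scale_ = np.sqrt(var[keep])
        Z = (A[:, keep] - self.mean_) / self.scale_
        corr = (Z * w[:, None]).T @ Z / w.sum()
        evals, evecs = np.linalg.eigh(corr)
        self.explained_variance_ratio_ = float(evals[-1] / evals.sum())
        v = evecs[:, -1]
        score = Z @ v
        # orientation: richer households must score higher
        if self.orient_by is not None:
            if isinstance(X, pd.DataFrame):
                ref = F[self.orient_by].to_numpy(dtype=float)
            else:
                ref = A[:, int(self.orient_by)]
        else:
            ref = A[:, keep].sum(axis=1)
        refc = ref - np.average(ref, weights=w)
        align = float(np.average(refc * score, weights=w))
        if align < 0:
            v = -v
        elif align == 0 and v.sum() < 0:
            v = -v  # degenerate orientation: deterministic fallback
        self.loadings_ = v
        self._fit_weights = w
        return self

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "loadings_")
        F = self._to_frame(X)
        if isinstance(X, pd.DataFrame):
            A = F[self.columns_].to_numpy(dtype=float)
        else:
            A = F.to_numpy(dtype=float)
            keep = [i for i, c in enumerate(self._to_frame(X).columns) if c in self.columns_]
            A = A[:, keep]
        Z = (A - self.mean_) / self.scale_
        return Z @ self.loadings_


def fractional_rank(score, weights=None) -> np.ndarray:
    """Weighted fractional rank with the midpoint convention.

    Sorting by score ascending, ``r_i = (W_<i + w_i / 2) / W`` where ``W_<i``
    is the total weight of strictly poorer rows; rows tied on the score share
    the weighted mean rank of their tie group. The weighted mean of the
    result is exactly 0.5 for any positive weighting.
    """
    score = np.asarray(score, dtype=float)
    if score.size == 0:
        raise ValueError("empty input")
    w = as_weights(weights, score.shape[0])
    order = np.argsort(score, kind="stable")
    s, ws = score[order], w[order]
    total = ws.sum()
    cum = np.cumsum(ws)
    r_sorted = (cum - ws / 2.0) / total
    # average ranks within tie groups (weighted mean keeps the global mean at 0.5)
    group_id = np.cumsum(np.r_[True, s[1:] != s[:-1]]) - 1
    gw = np.bincount(group_id, weights=ws)
    gwr = np.bincount(group_id, weights=ws * r_sorted)
    r_sorted = (gwr / gw)[group_id]
    r = np.empty_like(r_sorted)
    r[order] = r_sorted
    return r


def wealth_quintiles(score, weights=None, n_groups: int = 5) -> np.ndarray:
    """Weighted quantile-group labels 1..n_groups (1 = poorest).

    Cut points are placed on cumulative weight; each tie group is assigned
    as a block, with groups landing exactly on a cut point going to the
    lower quantile. Each group's weight share is within one row's weight of
    ``1 / n_groups``.
    """
    score = np.asarray(score, dtype=float)
    if score.size == 0:
        raise ValueError("empty input")
    w = as_weights(weights, score.shape[0])
    order = np.argsort(score, kind="stable")
    s, ws = score[order], w[order]
    total = ws.sum()
    group_id = np.cumsum(np.r_[True, s[1:] != s[:-1]]) - 1
    cum_hi = np.cumsum(np.bincount(group_id, weights=ws))  # cum weight through each tie group
    frac_hi = cum_hi[group_id] / total
    q = np.ceil(n_groups * frac_hi - 1e-9).astype(int)
    q = np.clip(q, 1, n_groups)
    out = np.empty_like(q)
    out[order] = q
    return out


def rank_households(assets, weights=None, *, weighted_pca: bool = True, orient_by=None,
                    score=None) -> WealthRanking:
    """Build the full wealth ranking (score, quintile, fractional rank).

    ``score`` may be supplied directly (e.g. a survey's own pre-computed
    wealth index), in which case ``assets`` is ignored.
    """
    if score is None:
        idx = WealthIndex(weighted=weighted_pca, orient_by=orient_by)
        score = idx.fit(assets, sample_weight=weights).transform(assets)
    score = np.asarray(score, dtype=float)
    w = as_weights(weights, score.shape[0])
    return WealthRanking(
        score=score,
        quintile=wealth_quintiles(score, w),
        rank=fractional_rank(score, w),
        weights=w,
    )
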