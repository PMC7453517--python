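"""Regression-based decomposition of a concentration index (Wagstaff-style).

Given a linear-additive model h = alpha + sum_k beta_k x_k + e, the
concentration index of the outcome splits as

    CI = sum_k eta_k C_k + GC_e / mu,    eta_k = (beta_k xbar_k) / mu,

with C_k the standard concentration index of determinant k and GC_e the
generalized concentration index of the residual. For a logit, beta_k is
replaced by the average marginal effect dy/dx, which makes the additivity
hold only up to an approximation residual; with the LPM it is exact.
Percent contributions divide each share eta_k C_k by the explained part
sum_k eta_k C_k (not the total CI) and multiply by 100. The Erreygers-scaled
variant multiplies every share by 4 mu, leaving percent shares unchanged.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from ._weights import as_weights, wcov, wmean
from .concentration import concentration_index, generalized_concentration
from .outcome import LinearProbabilityModel, WeightedLogit

__all__ = [
    "elasticity",
    "contribution",
    "percent_contribution",
    "decompose_from_components",
    "CIDecomposition",
    "decompose_ci",
    "format_report",
]


def elasticity(dydx: float, xbar: float, mu: float) -> float:
    """Elasticity eta_k = dydx * xbar / mu of the outcome w.r.t. determinant k."""
    if not mu > 0:
        raise ValueError(f"outcome mean must be positive, got {mu}")
    return dydx * xbar / mu


def contribution(eta: float, c_k: float) -> float:
    """Share of determinant k in the explained CI: eta_k * C_k."""
    return eta * c_k


def percent_contribution(share_k: float, all_shares) -> float:
    """100 * share_k / sum(all shares); the explained CI is the denominator."""
    total = float(np.sum(all_shares))
    if total == 0:
        raise ZeroDivisionError("explained concentration index is zero")
    return 100.0 * share_k / total


def decompose_from_components(dydx, means, c_k, mu: float, ci: float | None = None) -> pd.DataFrame:
    """Run the elasticity -> share -> %-share arithmetic from its components.

    This is the pure bookkeeping chain: it takes per-determinant marginal
    effects, weighted means and determinant concentration indices — whether
    estimated from microdata or transcribed from a published table — and
    returns the full per-determinant decomposition table.

    Parameters
    ----------
    dydx, means, c_k : Series or array-like
        Aligned per-determinant components (Series are aligned on index).
    mu : float
        Outcome prevalence (weighted mean).
    ci : float, optional
        Outcome concentration index; when given, the table's ``attrs`` carry
        the explained CI, the residual CI - sum_k eta_k C_k and the
        Erreygers-scaled versions of both.
    """
    dydx = pd.Series(dydx, dtype=float)
    means = pd.Series(means, dtype=float).reindex(dydx.index)
    c_k = pd.Series(c_k, dtype=float).reindex(dydx.index)
    eta = dydx * means / mu
    share = eta * c_k
    zero_mean = means == 0
    if zero_mean.any():
        warnings.warn(f"determinants with zero weighted mean, contribution forced to 0: "
                      f"{list(dydx.index[zero_mean])}", UserWarning)
        share = share.where(~zero_mean, 0.0)
    explained = float(share.sum())
    table = pd.DataFrame({
        "dydx": dydx,
        "mean": means,
        "c_k": c_k,
        "elasticity": eta,
        "share": share,
        "pct_share": 100.0 * share / explained,
        "share_erreygers": 4.0 * mu * share,
    })
    table.attrs["mu"] = float(mu)
    table.attrs["explained_ci"] = explained
    table.attrs["explained_erreygers"] = 4.0 * mu * explained
    if ci is not None:
        table.attrs["ci"] = float(ci)
        table.attrs["residual"] = float(ci) - explained
        table.attrs["erreygers"] = 4.0 * mu * float(ci)
        table.attrs["residual_erreygers"] = 4.0 * mu * (float(ci) - explained)
    return table


class CIDecomposition(BaseEstimator):
    """Decompose the outcome's wealth-related CI into determinant contributions.

    Parameters
    ----------
    model : {"logit", "lpm"}, default "logit"
        Outcome model supplying the marginal effects dy/dx. ``"logit"`` uses
        weighted maximum likelihood with average marginal effects (the
        linearization for a binary outcome); ``"lpm"`` uses weighted least
        squares, for which the decomposition is exactly additive.
    me_at_means : bool, default False
        Evaluate logit marginal effects at the weighted covariate means
        instead of averaging over the sample.

    Attributes
    ----------
    table_ : DataFrame
        Per-determinant dy/dx, weighted mean, C_k, elasticity, share,
        %-share and Erreygers-scaled share; ``table_.attrs`` carry mu, CI,
        explained CI and residual on both scales.
    mu_, ci_, erreygers_ : float
        Outcome prevalence and its standard / Erreygers-normalized CI.
    explained_ci_, residual_ : float
        sum_k eta_k C_k and CI minus it (= GC_e / mu under the LPM).
    model_ : fitted estimator
        The underlying :class:`WeightedLogit` or
        :class:`LinearProbabilityModel`.
    """

    def __init__(self, model: str = "logit", me_at_means: bool = False):
        self.model = model
        self.me_at_means = me_at_means

    def fit(self, X, y, rank=None, sample_weight=None):
        if rank is None:
            raise ValueError("rank (weighted fractional wealth rank) is required")
        y = np.asarray(y, dtype=float)
        rank = np.asarray(rank, dtype=float)
        w = as_weights(sample_weight, len(y))
        if self.model == "logit":
            est = WeightedLogit(at_means=self.me_at_means)
        elif self.model == "lpm":
            est = LinearProbabilityModel()
        else:
            raise ValueError("model must be 'logit' or 'lpm'")
        est.fit(X, y, sample_weight=w)
        dydx = est.average_marginal_effects()
        Xf = est._X
        means = pd.Series(np.average(Xf.to_numpy(), axis=0, weights=w), index=Xf.columns)
        c_k = pd.Series(
            {c: (concentration_index(Xf[c], rank, w, bounds=None).ci if means[c] != 0 else np.nan)
             for c in Xf.columns})
        out = concentration_index(y, rank, w, bounds=(0.0, 1.0))
        self.mu_ = out.mu
        self.ci_ = out.ci
        self.erreygers_ = out.erreygers
        self.table_ = decompose_from_components(dydx, means, c_k, mu=out.mu, ci=out.ci)
        self.explained_ci_ = self.table_.attrs["explained_ci"]
        self.residual_ = self.table_.attrs["residual"]
        self.model_ = est
        resid = y - est.predict_proba(X)
        self.gc_residual_ = generalized_concentration(resid, rank, w)
        self.rank_ = rank
        self.weights_ = w
        return self

    @property
    def decomposition_table(self) -> pd.DataFrame:
        check_is_fitted(self, "table_")
        return self.table_


def decompose_ci(X, y, rank, sample_weight=None, **kwargs) -> pd.DataFrame:
    """Functional wrapper: fitted decomposition table (see :class:`CIDecomposition`)."""
    return CIDecomposition(**kwargs).fit(X, y, rank=rank, sample_weight=sample_weight).table_


#: print rounding used in report CSVs: 3 decimals for dy/dx, C_k and
#: elasticity, 4 for shares, 1 for percent shares
_REPORT_DECIMALS = {"dydx": 3, "mean": 3, "c_k": 3, "elasticity": 3,
                    "share": 4, "share_erreygers": 4, "pct_share": 1}


def format_report(table: pd.DataFrame) -> pd.DataFrame:
    """Apply report rounding to a decomposition table."""
    out = table.copy()
    for col, nd in _REPORT_DECIMALS.items():
        if col in out.columns:
            out[col] = out[col].round(nd)
    return out
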