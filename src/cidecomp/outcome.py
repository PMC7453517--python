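"""Weighted outcome models: logit with average marginal effects, and the LPM.

The decomposition of a concentration index needs a linear-additive model of
the outcome on its determinants. For a binary outcome the logit is fitted by
weighted maximum likelihood and linearized through marginal effects on the
probability scale: the average marginal effect (AME) of a continuous
regressor is the weighted mean of p_i (1 - p_i) beta_k, and of a dummy the
weighted mean counterfactual difference p(x_k = 1) - p(x_k = 0). The linear
probability model (LPM) is kept as the exactly-additive alternative.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from ._weights import as_weights

__all__ = ["WeightedLogit", "LinearProbabilityModel", "CollinearityError", "fit_logit"]


class CollinearityError(ValueError):
    """Design matrix is rank-deficient; message names the redundant columns."""


def _as_frame(X) -> pd.DataFrame:
    if isinstance(X, pd.DataFrame):
        return X.astype(float)
    X = np.asarray(X, dtype=float)
    return pd.DataFrame(X, columns=[f"x{i}" for i in range(X.shape[1])])


def _check_collinearity(X: pd.DataFrame, w: np.ndarray) -> None:
    A = X.to_numpy() * np.sqrt(w)[:, None]
    A = np.column_stack([np.sqrt(w), A])
    rank = np.linalg.matrix_rank(A)
    if rank == A.shape[1]:
        return
    # name the offenders: columns lying in the span of the preceding ones
    bad = []
    cols = [np.sqrt(w)]
    for j, name in enumerate(X.columns):
        v = A[:, j + 1]
        B = np.column_stack(cols)
        resid = v - B @ np.linalg.lstsq(B, v, rcond=None)[0]
        if np.linalg.norm(resid) < 1e-8 * max(1.0, np.linalg.norm(v)):
            bad.append(str(name))
        else:
            cols.append(v)
    raise CollinearityError(f"perfectly collinear columns: {bad}")


def _is_dummy(col: np.ndarray) -> bool:
    return np.isin(np.unique(col), (0.0, 1.0)).all()


class WeightedLogit(BaseEstimator):
    """Sampling-weighted logistic regression with marginal effects.

    Parameters
    ----------
    at_means : bool, default False
        Report marginal effects evaluated at the weighted covariate means
        instead of averaged over the sample (AME, the default).
    discrete_dummies : bool, default True
        Use the discrete-change effect for 0/1 regressors; with ``False``
        the derivative formula is applied to every column.
    maxiter : int
        IRLS iteration cap.

    Attributes
    ----------
    coef_ : pandas Series
        Log-odds slopes per determinant column.
    intercept_ : float
    odds_ratios_ : pandas Series
    llf_, llnull_, pseudo_r2_ : float
        Log-likelihood, null log-likelihood and McFadden pseudo R^2, on
        weights normalized to the sample size.
    converged_ : bool
    """

    def __init__(self, at_means: bool = False, discrete_dummies: bool = True, maxiter: int = 100):
        self.at_means = at_means
        self.discrete_dummies = discrete_dummies
        self.maxiter = maxiter

    def fit(self, X, y, sample_weight=None):
        Xf = _as_frame(X)
        y = np.asarray(y, dtype=float)
        w = as_weights(sample_weight, len(Xf))
        w = w * (len(w) / w.sum())  # normalize to sample size; point estimates unaffected
        _check_collinearity(Xf, w)
        design = sm.add_constant(Xf, has_constant="raise")
        model = sm.GLM(y, design, family=sm.families.Binomial(), var_weights=w)
        res = model.fit(maxiter=self.maxiter)
        self.converged_ = bool(res.converged)
        if not self.converged_:
            raise RuntimeError(
                f"logit did not converge in {self.maxiter} iterations; "
                f"|score| = {np.abs(res.model.score(res.params)).max():.3g}")
        if np.abs(res.params.iloc[1:]).max() > 30:
            sep = res.params.iloc[1:].abs().idxmax()
            raise RuntimeError(f"apparent complete separation on column '{sep}'")
        self.result_ = res
        self.intercept_ = float(res.params["const"])
        self.coef_ = res.params.drop("const")
        self.odds_ratios_ = np.exp(self.coef_)
        self.llf_ = float(res.llf)
        null = sm.GLM(y, np.ones((len(y), 1)), family=sm.families.Binomial(),
                      var_weights=w).fit()
        self.llnull_ = float(null.llf)
        self.pseudo_r2_ = 1.0 - self.llf_ / self.llnull_
        self._X, self._w = Xf, w
        return self

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "coef_")
        Xf = _as_frame(X)[self.coef_.index]
        eta = self.intercept_ + Xf.to_numpy() @ self.coef_.to_numpy()
        return 1.0 / (1.0 + np.exp(-eta))

    def average_marginal_effects(self, X=None, sample_weight=None) -> pd.Series:
        """Marginal effects on the probability scale, one per column.

        Defaults to the training sample and weights. At-means evaluation is
        controlled by the ``at_means`` parameter.
        """
        check_is_fitted(self, "coef_")
        Xf = self._X if X is None else _as_frame(X)[self.coef_.index]
        w = self._w if X is None else as_weights(sample_weight, len(Xf))
        if self.at_means:
            xbar = pd.Series(np.average(Xf.to_numpy(), axis=0, weights=w), index=Xf.columns)
            Xeval = pd.DataFrame([xbar])
            weval = np.ones(1)
        else:
            Xeval, weval = Xf, w
        p = self.predict_proba(Xeval)
        out = {}
        for name in Xf.columns:
            beta = self.coef_[name]
            col = Xf[name].to_numpy()
            if self.discrete_dummies and _is_dummy(col):
                X1 = Xeval.copy(); X1[name] = 1.0
                X0 = Xeval.copy(); X0[name] = 0.0
                out[name] = float(np.average(self.predict_proba(X1) - self.predict_proba(X0),
                                             weights=weval))
            else:
                out[name] = float(np.average(p * (1 - p) * beta, weights=weval))
        return pd.Series(out, name="dydx")


class LinearProbabilityModel(BaseEstimator):
    """Weighted least-squares linear probability model.

    Marginal effects equal the coefficients, so the decomposition identity
    sum_k eta_k C_k + GC_e / mu = CI holds exactly.
    """

    def fit(self, X, y, sample_weight=None):
        Xf = _as_frame(X)
        y = np.asarray(y, dtype=float)
        w = as_weights(sample_weight, len(Xf))
        _check_collinearity(Xf, w)
        design = sm.add_constant(Xf, has_constant="raise")
        res = sm.WLS(y, design, weights=w).fit()
        self.result_ = res
        self.intercept_ = float(res.params["const"])
        self.coef_ = res.params.drop("const")
        self._X, self._w = Xf, w
        return self

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "coef_")
        Xf = _as_frame(X)[self.coef_.index]
        return self.intercept_ + Xf.to_numpy() @ self.coef_.to_numpy()

    def average_marginal_effects(self, X=None, sample_weight=None) -> pd.Series:
        check_is_fitted(self, "coef_")
        return self.coef_.rename("dydx")

    def residuals(self) -> np.ndarray:
        check_is_fitted(self, "coef_")
        return np.asarray(self.result_.resid)


def fit_logit(X, y, sample_weight=None, **kwargs) -> WeightedLogit:
    """Thin functional wrapper over :class:`WeightedLogit`."""
    return WeightedLogit(**kwargs).fit(X, y, sample_weight=sample_weight)
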