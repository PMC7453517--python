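"""Blinder-Oaxaca decomposition of the change in a concentration index.

Between an early wave A and a late wave B, the explained concentration
index changes by

    sum_k (eta_kB C_kB - eta_kA C_kA)

and each determinant's change splits exactly into an elasticity-change part
and an inequality-change part. Two reference weightings satisfy the same
row identity:

    scheme "paper":  C_kA * d_eta_k  +  eta_kB * d_C_k
    scheme "table4": C_kB * d_eta_k  +  eta_kA * d_C_k

(d_eta = eta_B - eta_A, d_C = C_B - C_A). The two schemes differ per row by
exactly -d_eta * d_C. Percent shares divide each component by the explained
total change. On an outcome whose inequality is positive and falling, a
positive per-determinant total means the determinant contributed to the
decline.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["oaxaca_component", "decompose_change", "OAXACA_SCHEMES"]

OAXACA_SCHEMES = ("paper", "table4")


def oaxaca_component(eta_a, eta_b, c_a, c_b, scheme: str = "table4"):
    """Elasticity-change and inequality-change components for one determinant.

    Returns ``(elasticity_component, ci_component)``; their sum equals
    ``eta_b * c_b - eta_a * c_a`` under either scheme.
    """
    if scheme not in OAXACA_SCHEMES:
        raise ValueError(f"scheme must be one of {OAXACA_SCHEMES}, got {scheme!r}")
    d_eta = np.asarray(eta_b, dtype=float) - np.asarray(eta_a, dtype=float)
    d_c = np.asarray(c_b, dtype=float) - np.asarray(c_a, dtype=float)
    if scheme == "paper":
        return np.asarray(c_a, dtype=float) * d_eta, np.asarray(eta_b, dtype=float) * d_c
    return np.asarray(c_b, dtype=float) * d_eta, np.asarray(eta_a, dtype=float) * d_c


def decompose_change(table_a: pd.DataFrame, table_b: pd.DataFrame,
                     scheme: str = "table4") -> pd.DataFrame:
    """Per-determinant decomposition of the change in explained inequality.

    Parameters
    ----------
    table_a, table_b : DataFrame
        Decomposition tables of the early and late wave (from
        :class:`~cidecomp.decomposition.CIDecomposition` or
        :func:`~cidecomp.decomposition.decompose_from_components`), sharing
        the same determinant index and carrying ``elasticity`` and ``c_k``
        columns.
    scheme : {"table4", "paper"}
        Reference weighting (see module docstring).

    Returns
    -------
    DataFrame
        Columns ``d_eta``, ``d_c``, ``elasticity_component``,
        ``ci_component``, ``total`` and percent shares of each relative to
        the explained change; ``attrs['delta_ci_explained']`` holds the
        explained change, and ``attrs['delta_ci']`` the change in the
        outcome CI when both tables carry one.
    """
    only_a = table_a.index.difference(table_b.index)
    only_b = table_b.index.difference(table_a.index)
    if len(only_a) or len(only_b):
        raise ValueError(f"determinant sets differ between waves: "
                         f"only in A: {list(only_a)}; only in B: {list(only_b)}")
    a = table_a
    b = table_b.loc[a.index]
    eta_a, eta_b = a["elasticity"], b["elasticity"]
    c_a, c_b = a["c_k"], b["c_k"]
    ec, cc = oaxaca_component(eta_a, eta_b, c_a, c_b, scheme=scheme)
    total = eta_b * c_b - eta_a * c_a
    delta_explained = float(total.sum())
    out = pd.DataFrame({
        "eta_a": eta_a, "eta_b": eta_b, "c_a": c_a, "c_b": c_b,
        "d_eta": eta_b - eta_a, "d_c": c_b - c_a,
        "elasticity_component": ec, "ci_component": cc, "total": total,
        "pct_elasticity": 100.0 * ec / delta_explained,
        "pct_ci": 100.0 * cc / delta_explained,
        "pct_total": 100.0 * total / delta_explained,
    })
    out.attrs["scheme"] = scheme
    out.attrs["delta_ci_explained"] = delta_explained
    if "ci" in a.attrs and "ci" in b.attrs:
        out.attrs["delta_ci"] = b.attrs["ci"] - a.attrs["ci"]
    # sign convention: change is late minus early, so when inequality falls a
    # determinant contributed to the decline iff its total moves with the
    # explained change, i.e. its percent share is positive
    out.attrs["declining_contributors"] = list(out.index[out["pct_total"] > 0])
    return out
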