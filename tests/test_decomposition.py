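"""Decomposition of the concentration index into determinant contributions."""

import numpy as np
import pandas as pd
import pytest

from cidecomp.datasets import benchmark_components
from cidecomp.decomposition import (CIDecomposition, contribution,
                                    decompose_from_components, elasticity,
                                    format_report, percent_contribution)
from cidecomp.survey import recode_determinants
from cidecomp.wealth import fractional_rank, rank_households

from _published_expectations import DERIVED


class TestElasticityChain:
    def test_elasticity_published_cells(self):
        # rural Upper Egypt and modern-toilet rows of the early benchmark wave
        assert elasticity(-0.198, 0.294, 0.304) == pytest.approx(-0.191, abs=0.001)
        assert elasticity(0.132, 0.216, 0.304) == pytest.approx(0.094, abs=0.001)

    def test_elasticity_zero_effect(self):
        assert elasticity(0.0, 123.4, 0.5) == 0.0

    def test_elasticity_nonpositive_mean_errors(self):
        with pytest.raises(ValueError):
            elasticity(0.1, 0.2, 0.0)

    def test_contribution_published_cells(self):
        assert contribution(-0.191, -0.437) == pytest.approx(0.0836, abs=0.0005)
        assert contribution(0.094, 0.732) == pytest.approx(0.0686, abs=0.0005)
        assert contribution(0.7, 0.0) == 0.0

    def test_percent_contribution(self):
        shares = [float(v[1]) for v in DERIVED["1995"].values()]
        rural_upper = DERIVED["1995"]["region_rural_upper"][1]
        assert percent_contribution(rural_upper, shares) == pytest.approx(25.3, abs=0.2)
        assert percent_contribution(0.05, [0.05]) == 100.0
        assert percent_contribution(0.0, shares) == 0.0
        with pytest.raises(ZeroDivisionError):
            percent_contribution(0.1, [0.2, -0.2])


@pytest.mark.parametrize("wave", ["1995", "2014"])
def test_benchmark_chain_reproduces_published_derived_columns(wave):
    """Feeding the published dy/dx, means and determinant CIs through the
    elasticity -> share -> %-share chain reproduces the published derived
    columns for every determinant."""
    comp = benchmark_components(wave)
    table = decompose_from_components(comp["dydx"], comp["mean"], comp["c_k"],
                                      mu=comp.attrs["mu"], ci=comp.attrs["ci"])
    for det, (eta, share, pct) in DERIVED[wave].items():
        assert table.loc[det, "elasticity"] == pytest.approx(eta, abs=0.004), det
        assert table.loc[det, "share"] == pytest.approx(share, abs=0.0005), det
        assert table.loc[det, "pct_share"] == pytest.approx(pct, abs=0.3), det
    assert table["pct_share"].sum() == pytest.approx(100.0, abs=1e-9)
    # residual carried in attrs: CI minus explained part
    assert table.attrs["residual"] == pytest.approx(
        comp.attrs["ci"] - table["share"].sum(), abs=1e-12)


@pytest.fixture(scope="module")
def fitted(small_wave):
    rm = recode_determinants(small_wave)
    ranking = rank_households(small_wave.assets, rm.weights)
    dec = CIDecomposition(model="lpm")
    return dec.fit(rm.X, rm.y, rank=ranking.rank, sample_weight=rm.weights), rm, ranking


class TestCIDecompositionEstimator:

    def test_lpm_decomposition_is_exactly_additive(self, fitted):
        dec, rm, ranking = fitted
        gc_over_mu = dec.gc_residual_ / dec.mu_
        assert dec.explained_ci_ + gc_over_mu == pytest.approx(dec.ci_, abs=1e-10)
        assert dec.residual_ == pytest.approx(gc_over_mu, abs=1e-10)

    def test_shares_sum_to_explained_and_pct_to_100(self, fitted):
        dec, _, _ = fitted
        assert dec.table_["share"].sum() == pytest.approx(dec.explained_ci_, abs=1e-14)
        assert dec.table_["pct_share"].sum() == pytest.approx(100.0, abs=1e-9)

    def test_erreygers_scaled_shares(self, fitted):
        dec, _, _ = fitted
        np.testing.assert_allclose(dec.table_["share_erreygers"],
                                   4 * dec.mu_ * dec.table_["share"], atol=1e-14)
        assert dec.erreygers_ == pytest.approx(4 * dec.mu_ * dec.ci_, abs=1e-12)

    def test_zeroing_one_determinant_ci_removes_its_share(self, fitted):
        dec, _, _ = fitted
        t = dec.table_
        c_mod = t["c_k"].copy()
        c_mod["toilet_modern"] = 0.0
        t2 = decompose_from_components(t["dydx"], t["mean"], c_mod, mu=dec.mu_)
        assert t2.attrs["explained_ci"] == pytest.approx(
            dec.explained_ci_ - t.loc["toilet_modern", "share"], abs=1e-12)

    def test_logit_and_lpm_agree_on_sign_pattern(self, small_wave):
        rm = recode_determinants(small_wave)
        ranking = rank_households(small_wave.assets, rm.weights)
        logit = CIDecomposition(model="logit").fit(rm.X, rm.y, rank=ranking.rank,
                                                   sample_weight=rm.weights)
        assert np.sign(logit.table_["share"]).equals(
            np.sign(logit.table_["elasticity"] * logit.table_["c_k"]))

    def test_rank_required(self, small_wave):
        rm = recode_determinants(small_wave)
        with pytest.raises(ValueError, match="rank"):
            CIDecomposition().fit(rm.X, rm.y, sample_weight=rm.weights)


def test_null_process_has_near_zero_shares(rng):
    """Outcome independent of wealth and of all determinants: every share
    and the outcome CI itself are statistical zeros."""
    n = 4000
    X = pd.DataFrame({"a": rng.binomial(1, 0.4, n).astype(float),
                      "b": rng.binomial(1, 0.6, n).astype(float)})
    y = rng.binomial(1, 0.5, n)
    rank = fractional_rank(rng.normal(size=n))
    dec = CIDecomposition(model="lpm").fit(X, y, rank=rank)
    assert abs(dec.ci_) < 0.05
    assert dec.table_["share"].abs().max() < 0.01


def test_zero_mean_determinant_contribution_forced_zero():
    dydx = pd.Series({"a": 0.5, "b": 0.2})
    means = pd.Series({"a": 0.4, "b": 0.0})
    c_k = pd.Series({"a": 0.3, "b": np.nan})
    with pytest.warns(UserWarning, match="zero weighted mean"):
        t = decompose_from_components(dydx, means, c_k, mu=0.5)
    assert t.loc["b", "share"] == 0.0


def test_format_report_rounding():
    comp = benchmark_components("1995")
    t = decompose_from_components(comp["dydx"], comp["mean"], comp["c_k"],
                                  mu=comp.attrs["mu"])
    r = format_report(t)
    assert r.loc["region_rural_upper", "elasticity"] == -0.191
    assert r.loc["region_rural_upper", "pct_share"] == pytest.approx(25.4, abs=0.1)
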