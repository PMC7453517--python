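"""Published benchmark inputs for the decomposition arithmetic.

A national Egyptian two-wave (1995 and 2014 DHS rounds) analysis of
wealth-related inequality in regular antenatal care (four or more visits)
published, for every determinant, the marginal effect dy/dx, the weighted
mean and the determinant concentration index, together with the outcome
prevalence and outcome concentration index per wave. Those per-determinant
components are inputs to the elasticity / share / %-share chain and to the
between-wave Oaxaca decomposition, so they serve as a desk-scale benchmark:
feeding them through :func:`cidecomp.decomposition.decompose_from_components`
and :func:`cidecomp.oaxaca.decompose_change` must reproduce the published
derived columns.

Values are transcribed at their printed precision (3 decimals).
"""

from __future__ import annotations

import pandas as pd

__all__ = ["benchmark_components", "BENCHMARK_MU", "BENCHMARK_CI", "BENCHMARK_DETERMINANTS"]

#: outcome prevalence (weighted mean of the binary outcome) per wave
BENCHMARK_MU = {"1995": 0.304, "2014": 0.829}

#: outcome concentration index per wave; the relative decline is 66.1%
BENCHMARK_CI = {"1995": 0.507, "2014": 0.172}

# determinant: (dydx_1995, c_1995, mean_1995, dydx_2014, c_2014, mean_2014)
_COMPONENTS = {
    "age_20_24":            (0.025, -0.018, 0.274,  0.007,  0.004, 0.305),
    "age_25_29":            (0.078,  0.067, 0.291,  0.029,  0.030, 0.324),
    "age_30_34":            (0.094,  0.026, 0.189,  0.046,  0.010, 0.192),
    "age_35_39":            (0.098, -0.016, 0.107,  0.038, -0.027, 0.086),
    "age_40p":              (0.114, -0.079, 0.039,  0.073, -0.080, 0.020),
    "edu_primary":          (0.048, -0.019, 0.220,  0.015, -0.205, 0.089),
    "edu_secondary":        (0.153,  0.406, 0.281,  0.057,  0.036, 0.573),
    "edu_higher":           (0.271,  0.812, 0.057,  0.115,  0.446, 0.156),
    "husband_edu_primary":  (0.050, -0.130, 0.279,  0.047, -0.133, 0.136),
    "husband_edu_secondary":(0.054,  0.235, 0.334,  0.057, -0.009, 0.566),
    "husband_edu_higher":   (0.099,  0.654, 0.109,  0.087,  0.365, 0.166),
    "region_urban_lower":   (-0.023, 0.430, 0.103, -0.001,  0.616, 0.093),
    "region_rural_lower":   (-0.142, -0.124, 0.300, -0.021, -0.154, 0.394),
    "region_urban_upper":   (-0.054,  0.307, 0.113, -0.064,  0.479, 0.111),
    "region_rural_upper":   (-0.198, -0.437, 0.294, -0.093, -0.438, 0.287),
    "region_frontier":      (-0.142,  0.142, 0.010, -0.081,  0.123, 0.009),
    "toilet_modern":        (0.132,  0.732, 0.216,  0.023,  0.350, 0.523),
    "terminated_pregnancy": (0.080, -0.022, 0.267,  0.030, -0.066, 0.207),
    "interval_gt24":        (0.055,  0.027, 0.788,  0.048,  0.011, 0.845),
    "single_birth":         (-0.036, 0.001, 0.984, -0.069,  0.001, 0.978),
    "birth_order":          (-0.016, -0.115, 3.714, -0.024, -0.074, 2.675),
    "prev_medical":         (0.113,  0.250, 0.110, -0.009,  0.012, 0.286),
    "prev_csection":        (-0.004, 0.328, 0.019,  0.077,  0.085, 0.158),
    "prev_alive":           (-0.087, -0.008, 0.750, -0.103, -0.028, 0.758),
}

BENCHMARK_DETERMINANTS = tuple(_COMPONENTS)


def benchmark_components(wave: str) -> pd.DataFrame:
    """Published per-determinant components for ``wave`` ("1995" or "2014").

    Returns a DataFrame indexed by determinant with columns ``dydx``,
    ``c_k`` and ``mean``; ``attrs`` carry ``mu`` and ``ci`` of the outcome.
    """
    if wave not in BENCHMARK_MU:
        raise ValueError(f"wave must be one of {tuple(BENCHMARK_MU)}, got {wave!r}")
    off = 0 if wave == "1995" else 3
    df = pd.DataFrame(
        {det: vals[off:off + 3] for det, vals in _COMPONENTS.items()},
        index=["dydx", "c_k", "mean"],
    ).T
    df.attrs["mu"] = BENCHMARK_MU[wave]
    df.attrs["ci"] = BENCHMARK_CI[wave]
    return df
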