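"""Published derived columns of the benchmark analysis, at printed precision.

The package's :mod:`cidecomp.datasets` module carries the *inputs*
(dy/dx, determinant CI, weighted mean, outcome mu and CI per wave); the
dictionaries here carry the *derived* columns the publication printed —
elasticity, share and %-share per wave, and the per-determinant
change-decomposition components — used as frozen expectations when the
package recomputes the chains from the inputs.
"""

# wave -> determinant -> (elasticity, share, pct_share)
DERIVED = {
    "1995": {
        "age_20_24": (0.023, -0.0004, -0.1), "age_25_29": (0.074, 0.0050, 1.5),
        "age_30_34": (0.058, 0.0015, 0.5), "age_35_39": (0.034, -0.0005, -0.2),
        "age_40p": (0.015, -0.0012, -0.4),
        "edu_primary": (0.035, -0.0007, -0.2), "edu_secondary": (0.142, 0.0575, 17.4),
        "edu_higher": (0.051, 0.0410, 12.4),
        "husband_edu_primary": (0.046, -0.0059, -1.8),
        "husband_edu_secondary": (0.059, 0.0139, 4.2),
        "husband_edu_higher": (0.036, 0.0233, 7.1),
        "region_urban_lower": (-0.008, -0.0033, -1.0),
        "region_rural_lower": (-0.140, 0.0174, 5.3),
        "region_urban_upper": (-0.020, -0.0062, -1.9),
        "region_rural_upper": (-0.191, 0.0836, 25.3),
        "region_frontier": (-0.005, -0.0007, -0.2),
        "toilet_modern": (0.094, 0.0686, 20.8),
        "terminated_pregnancy": (0.070, -0.0016, -0.5),
        "interval_gt24": (0.142, 0.0039, 1.2), "single_birth": (-0.117, -0.0001, 0.0),
        "birth_order": (-0.199, 0.0228, 6.9),
        "prev_medical": (0.041, 0.0102, 3.1), "prev_csection": (0.000, -0.0001, 0.0),
        "prev_alive": (-0.215, 0.0017, 0.5),
    },
    "2014": {
        "age_20_24": (0.003, 0.0000, 0.0), "age_25_29": (0.011, 0.0003, 0.8),
        "age_30_34": (0.011, 0.0001, 0.3), "age_35_39": (0.004, -0.0001, -0.3),
        "age_40p": (0.002, -0.0001, -0.3),
        "edu_primary": (0.002, -0.0003, -0.8), "edu_secondary": (0.040, 0.0014, 3.4),
        "edu_higher": (0.022, 0.0096, 22.9),
        "husband_edu_primary": (0.008, -0.0010, -2.4),
        "husband_edu_secondary": (0.039, -0.0003, -0.8),
        "husband_edu_higher": (0.017, 0.0064, 15.2),
        "region_urban_lower": (0.000, -0.0001, -0.2),
        "region_rural_lower": (-0.010, 0.0016, 3.7),
        "region_urban_upper": (-0.008, -0.0041, -9.7),
        "region_rural_upper": (-0.032, 0.0141, 33.5),
        "region_frontier": (-0.001, -0.0001, -0.3),
        "toilet_modern": (0.015, 0.0051, 12.1),
        "terminated_pregnancy": (0.007, -0.0005, -1.2),
        "interval_gt24": (0.049, 0.0005, 1.2), "single_birth": (-0.081, -0.0001, -0.2),
        "birth_order": (-0.079, 0.0058, 13.9),
        "prev_medical": (-0.003, 0.0000, -0.1), "prev_csection": (0.015, 0.0013, 3.0),
        "prev_alive": (-0.094, 0.0026, 6.2),
    },
}

# determinant -> (d_eta, d_c, elasticity_comp, ci_comp, total, pct_e, pct_c, pct_total)
CHANGE = {
    "age_20_24": (-0.020, 0.022, 0.000, 0.000, 0.000, -0.1, 0.0, -0.15),
    "age_25_29": (-0.063, -0.038, -0.002, -0.003, -0.005, 0.6, 1.0, 1.62),
    "age_30_34": (-0.048, -0.016, 0.000, -0.001, -0.001, 0.2, 0.3, 0.48),
    "age_35_39": (-0.030, -0.011, 0.001, 0.000, 0.000, -0.3, 0.1, -0.15),
    "age_40p": (-0.013, -0.001, 0.001, 0.000, 0.001, -0.4, 0.0, -0.36),
    "edu_primary": (-0.033, -0.185, 0.007, -0.006, 0.000, -2.4, 2.3, -0.12),
    "edu_secondary": (-0.102, -0.370, -0.004, -0.052, -0.056, 1.3, 18.2, 19.49),
    "edu_higher": (-0.029, -0.366, -0.013, -0.019, -0.031, 4.5, 6.4, 10.91),
    "husband_edu_primary": (-0.038, -0.003, 0.005, 0.000, 0.005, -1.7, 0.0, -1.71),
    "husband_edu_secondary": (-0.020, -0.243, 0.000, -0.014, -0.014, -0.1, 5.0, 4.94),
    "husband_edu_higher": (-0.018, -0.288, -0.007, -0.010, -0.017, 2.3, 3.6, 5.86),
    "region_urban_lower": (0.007, 0.186, 0.005, -0.001, 0.003, -1.6, 0.5, -1.11),
    "region_rural_lower": (0.130, -0.030, -0.020, 0.004, -0.016, 7.0, -1.5, 5.50),
    "region_urban_upper": (0.012, 0.172, 0.006, -0.003, 0.002, -1.9, 1.2, -0.74),
    "region_rural_upper": (0.159, -0.001, -0.070, 0.000, -0.070, 24.2, -0.1, 24.16),
    "region_frontier": (0.004, -0.019, 0.000, 0.000, 0.001, -0.2, 0.0, -0.19),
    "toilet_modern": (-0.079, -0.382, -0.028, -0.036, -0.064, 9.6, 12.4, 22.08),
    "terminated_pregnancy": (-0.063, -0.044, 0.004, -0.003, 0.001, -1.4, 1.1, -0.37),
    "interval_gt24": (-0.093, -0.017, -0.001, -0.002, -0.003, 0.3, 0.8, 1.17),
    "single_birth": (0.036, 0.000, 0.000, 0.000, 0.000, 0.0, 0.0, -0.01),
    "birth_order": (0.120, 0.040, -0.009, -0.008, -0.017, 3.1, 2.8, 5.89),
    "prev_medical": (-0.044, -0.237, -0.001, -0.010, -0.010, 0.2, 3.4, 3.55),
    "prev_csection": (0.015, -0.243, 0.001, 0.000, 0.001, -0.4, 0.0, -0.46),
    "prev_alive": (0.122, -0.020, -0.003, 0.004, 0.001, 1.2, -1.5, -0.30),
}

#: published relative decline in the outcome CI between the waves, percent
CI_DECLINE_PCT = 66.1
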