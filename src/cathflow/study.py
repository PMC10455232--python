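"""Published device-level summaries used as calibration targets and inputs.

These are the printed performance summaries of the randomised crossover
comparison of the micro-hole zone catheter (MHZC) against a conventional
eyelet catheter (CEC): per-device model means, effect measures, haematuria
proportions, pressure extremes, and participant accounting.  The package
uses them in two ways: as the calibration surface for the synthetic
generator defaults, and as inputs to the arithmetic cross-checks (ratios of
printed means, differences of printed means, percent reductions) that the
validation suite recomputes.
"""

REPORTED = {
    # model-based mean flow-stop count per device
    "flow_stops_mean": {"MHZC": 0.17, "CEC": 1.09},
    # residual urine at the first flow-stop (mL)
    "rv1_mean": {"MHZC": 5.10, "CEC": 39.40},
    "rv1_mean_difference": 34.30,
    # post-catheterisation residual by bladder scan (mL)
    "postvoid_residual_mean": {"MHZC": 5.92, "CEC": 7.13},
    "postvoid_residual_mean_difference": 1.21,
    # device effect measures
    "flow_stop_rate_ratio": 0.16,
    "haematuria_odds_ratio": 0.26,
    # haematuria-positive proportions
    "haematuria_proportion": {"MHZC": 0.10, "CEC": 0.29},
    # intra-catheter pressure extremes (cmH2O)
    "pressure_min": {"MHZC": -87.7, "CEC": -423.2},
    # participant accounting
    "n_randomised": 42,
    "n_missing_visit2": 1,
    "mhzc_catheterisations_with_flow_stops": 4,
}
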