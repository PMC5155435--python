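{
  "schema_version": 1,
  "comment": "Calibrated free parameters of the quorum-sensing cascade model. Constrained parameters (D_s, k_e, k_b_ref, rho_ref, rho_R, D_x, S0) are derived in code from printed experimental anchors. Calibration objective: categorical match of the 4-level color score table, anchored on the observed minimum activating heights (10 mm at 1e4 cells/ml, 16 mm at 1e3 cells/ml, 96 h) and on score-table stability between 96 h and 120 h.",
  "units": {
    "alpha": "nM*ml/(cell*h)",
    "C_star": "nM",
    "m": "dimensionless",
    "A_tot": "nM/h",
    "k1": "1/(nM*h)",
    "k_m1": "1/h",
    "k2": "1/h",
    "thresholds_nM": "nM (cleaved product at the top node; level = number of thresholds strictly exceeded)"
  },
  "fitted": {
    "alpha": 5.2976e-05,
    "C_star": 5.0,
    "m": 1,
    "A_tot": 50.0,
    "k1": 1e-05,
    "k_m1": 1.0,
    "k2": 10.0
  },
  "thresholds_nM": [11800.0, 31500.0, 47500.0]
}
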