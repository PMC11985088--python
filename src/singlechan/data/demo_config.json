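{
  "seed": 7,
  "out_dir": "demo-out",
  "protocol": {
    "voltages": [160, 140, 100, 60, 20, -20, -60, -100, -140, -160],
    "per_voltage_duration": 20.0
  },
  "acquisition": {
    "fs": 5000,
    "filter_cutoff": 1000,
    "filter_order": 4,
    "noise_sd": 0.4,
    "oversample_factor": 10
  },
  "detector": {"order": 4, "threshold_lambda": 6.0},
  "fit": {"v_lo": 0.0, "v_hi": 100.0, "activity_voltage": -140.0},
  "growth": {
    "od0": 0.1,
    "baseline_rate": 0.0,
    "max_rate": 0.12,
    "half_sat_activity": 3.0,
    "carrying_capacity": 1.0,
    "noise_sd": 0.05
  },
  "analysis": {"timepoint": 48.0, "feature": "activity_meas", "welch": false, "holm": false},
  "n_replicates": 3,
  "panel": [
    {"label": "WT", "g_pS": 174.0, "po_m160": 0.034, "is_wt": true},
    {"label": "A", "g_pS": 165.0, "po_m160": 0.015},
    {"label": "C", "g_pS": 170.0, "po_m160": 0.42},
    {"label": "D", "g_pS": 190.0, "po_m160": 0.008},
    {"label": "E", "g_pS": 200.0, "po_m160": 0.02},
    {"label": "F", "g_pS": 160.0, "po_m160": 0.045},
    {"label": "G", "g_pS": 150.0, "po_m160": 0.02},
    {"label": "H", "g_pS": 90.0, "po_m160": 0.035},
    {"label": "I", "g_pS": 175.0, "po_m160": 0.03},
    {"label": "K", "g_pS": 60.0, "po_m160": 0.03},
    {"label": "M", "g_pS": 170.0, "po_m160": 0.006},
    {"label": "N", "g_pS": 155.0, "po_m160": 0.008},
    {"label": "P", "g_pS": 145.0, "po_m160": 0.45},
    {"label": "Q", "g_pS": 168.0, "po_m160": 0.06},
    {"label": "R", "g_pS": 40.5, "po_m160": 0.05},
    {"label": "S", "g_pS": 158.0, "po_m160": 0.01},
    {"label": "T", "g_pS": 172.0, "po_m160": 0.03},
    {"label": "V", "g_pS": 169.0, "po_m160": 0.025},
    {"label": "W", "g_pS": 152.0, "po_m160": 0.04},
    {"label": "Y", "g_pS": 163.0, "po_m160": 0.05}
  ]
}
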