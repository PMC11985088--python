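# Configuration and file formats

## Run configuration (JSON)

Consumed by `singlechan report|simulate|demo` and `singlechan.io.load_config`.
All sections are optional except `panel`; omitted keys take the defaults
shown. `--seed` on the command line overrides the file's `seed`.

```jsonc
{
  "seed": 0,                       // master seed; sub-seeds are spawned per genotype/voltage
  "out_dir": "singlechan-out",
  "log_level": "INFO",
  "n_replicates": 3,               // growth replicates per genotype
  "write_traces": false,           // also write per-voltage trace/event TSVs
  "growth_file": null,             // path to a measured growth CSV (skips growth simulation)

  "protocol": {
    "voltages": [160, 140, ..., -160],   // mV, distinct; default +160..-160 step -20
    "per_voltage_duration": 30.0         // s
  },
  "acquisition": {
    "fs": 5000,                    // Hz
    "filter_cutoff": 1000,         // Hz (-3 dB), must be < fs/2
    "filter_order": 4,
    "noise_sd": 0.4,               // pA in the recording bandwidth
    "oversample_factor": 10
  },
  "detector": {
    "order": 4,
    "threshold_lambda": 6.0,
    "dead_time": null,             // s; null -> 0.4 / filter_cutoff
    "edge_margin": null,           // samples; null -> ceil(2 fs / filter_cutoff)
    "open_level_hint": null        // pA; null -> two-pass auto estimate
  },
  "fit": {
    "v_lo": 0.0, "v_hi": 100.0,    // conductance fit range, mV
    "activity_voltage": -140.0
  },
  "growth": {                      // GrowthModel fields
    "od0": 0.1, "baseline_rate": 0.0, "max_rate": 0.12,
    "half_sat_activity": 3.0, "carrying_capacity": 1.0,
    "noise_sd": 0.05, "sample_times": [0, 6, 24, 48, 72]
  },
  "analysis": {
    "timepoint": 48.0,             // h, growth readout for correlation/classification
    "feature": "activity_meas",    // activity_meas | activity_true | activity_p140 | i_meas | po
    "welch": false, "holm": false
  },

  "panel": [                       // one entry per genotype; exactly one is_wt
    {
      "label": "WT",
      "g_pS": 174.0,               // unitary conductance
      "po_m160": 0.034,            // slow-gate stationary open fraction at -160 mV
      "po_p160": 0.005,            // optional; default po_m160 / 6.8
      "k_close0": 50.0,            // optional; slow-gate close rate at 0 mV (1/s)
      "flicker": true,             // optional; false pins the fast gate open
      "expression_factor": 1.0,    // optional hidden multiplier on activity
      "is_wt": true
    }
  ]
}
```

## Trace TSV

```
# genotype = WT
# voltage_mV = -140
# fs_hz = 5000
# filter_hz = 1000
time_s	current_pA
0.000000	-0.123
```

`fs_hz` is required on read; the time column must be strictly increasing
and is checked against `1/fs_hz` (warning above 0.1 % mismatch). Currents
carry 6 significant digits.

## Event TSV

Header `#` lines carry genotype, voltage, closed level, noise sd, open
level, and the detector settings, plus `t_total_s` and any warning flags;
columns are `event_index  state  start_s  duration_s  amplitude_pA` with
`state` ∈ {open, closed} and per-event mean levels in pA.

## Truth dwell TSV

`conducting_flag  start_s  duration_s` (1 = conducting), one file per
simulated trace, written by `singlechan simulate` next to each trace.

## Growth CSV

`genotype,replicate,time_h,od600` — tidy, one row per measurement; every
(genotype, replicate) needs a `time_h = 0` inoculation row.

## Summary TSV

One row per genotype:
`genotype  g_pS  fit_lo_mV  fit_hi_mV  mean_po  po_m140  i_meas_m140_pA
i_true_m140_pA  activity_meas_pA  activity_true_pA  activity_p140_pA  n`.
Genotypes whose records held too few resolvable open events for an i/V fit
appear as missing-value rows and are listed under `genotypes_without_fit`
in `report.json`.

All numeric output uses period decimal separators and fixed column order;
no file embeds timestamps, so identical inputs re-produce byte-identical
outputs.
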