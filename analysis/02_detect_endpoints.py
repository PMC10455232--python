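#!/usr/bin/env python
"""Detect flow-stops on every simulated trace and derive the endpoints.

Reads the trace CSVs written by 01_simulate_trial.py, runs the flow-stop
detector (flowrate < 0.8 mL/s for >= 2 s, terminal stop discounted), and
writes the per-catheterisation endpoints table results/demo/endpoints.csv:
flow-stop count, residual urine at the first flow-stop (RV1), peak suction
pressure, haematuria flag, and post-void residual.
"""

import pandas as pd

from cathflow.pipeline import RunConfig, detect_stage

if __name__ == "__main__":
    cfg = RunConfig(out_dir="results/demo", seed=42, n_subjects=42)
    path = detect_stage(cfg)
    df = pd.read_csv(path, comment="#")
    print(f"endpoints for {len(df)} catheterisations -> {path}")
    by_dev = df.groupby("device")[["n_flow_stops", "rv1"]].mean().round(2)
    print("\nobserved device means (detector output):")
    print(by_dev.to_string())
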