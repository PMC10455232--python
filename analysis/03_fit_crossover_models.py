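#!/usr/bin/env python
"""Fit the crossover mixed models and assemble the performance report.

Runs the full analysis on the detected endpoints: linear mixed model for
RV1 (with a Wilcoxon signed-rank robustness check), Poisson random-
intercept GLMM for flow-stop counts, logistic GLMM for haematuria, and the
fixed-sequence gatekeeping of the two co-primary endpoints.  Writes
results/demo/report.md and report.csv.
"""

from cathflow.pipeline import RunConfig, analyze_stage

if __name__ == "__main__":
    cfg = RunConfig(out_dir="results/demo", seed=42, n_subjects=42)
    report = analyze_stage(cfg)
    print(report.read_text())
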