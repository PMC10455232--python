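#!/usr/bin/env python
"""Simulate the demonstration crossover trial.

Generates a 42-subject block-randomised crossover comparing the micro-hole
zone catheter (MHZC) with a conventional eyelet catheter (CEC): one
pressure-volume trace and one clinical record per catheterisation, written
under results/demo/ for the downstream detection and analysis steps.
"""

from cathflow.pipeline import RunConfig, simulate_stage

SEED = 42

if __name__ == "__main__":
    cfg = RunConfig(out_dir="results/demo", seed=SEED, n_subjects=42)
    out = simulate_stage(cfg)
    print(f"wrote synthetic trial (seed {SEED}) to {out}")
    print("next: python analysis/02_detect_endpoints.py")
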