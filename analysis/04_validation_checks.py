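#!/usr/bin/env python
"""Scaled-down validation sweep: oracle equivalence, recovery, calibration.

A quick version of the checks in scripts/acceptance.py (300 traces, 200
null replicates, 150 effect replicates) for interactive use; writes
results/validation.csv.  The full-size run is scripts/acceptance.py.
"""

import pandas as pd

from cathflow.evaluation import (
    effect_recovery,
    gatekeeping_type1_error,
    validate_detector,
)

if __name__ == "__main__":
    rows = []

    det = validate_detector(n_traces=300, seed=7)
    rows.append(("detector_oracle_agreement", det.oracle_agreement_fraction, 300))
    rows.append(("injected_count_recovery", det.count_exact_fraction, 300))
    rows.append(("rv1_recovery_max_error_ml", det.rv1_max_abs_error_ml, 300))
    print(f"detector vs oracle: {det.oracle_agreement_fraction:.1%} agreement, "
          f"count recovery {det.count_exact_fraction:.1%}, "
          f"max RV1 error {det.rv1_max_abs_error_ml:.2f} mL")

    null = gatekeeping_type1_error(n_reps=200, seed=11)
    rows.append(("gatekeeping_type1_error", null["family_wise_rejection_rate"], 200))
    print(f"null family-wise rejection rate: "
          f"{null['family_wise_rejection_rate']:.3f} (target ~0.05)")

    rec = effect_recovery(n_reps=150, seed=13)
    rows.append(("recovered_rv1_difference_ml", rec["rv1_difference_mean"], 150))
    rows.append(("recovered_rate_ratio_median", rec["rate_ratio_median"], 150))
    print(f"recovered RV1 difference {rec['rv1_difference_mean']:.1f} mL "
          f"(true 34.3); rate-ratio median {rec['rate_ratio_median']:.3f} (true 0.16)")

    pd.DataFrame(rows, columns=["check", "value", "n"]).to_csv(
        "results/validation.csv", index=False
    )
    print("wrote results/validation.csv")
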