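"""Brute-force reference detector used to validate the production detector.

This walks the flowrate series sample by sample with explicit Python loops
and applies the flow-stop rules (onset, sub-threshold runs, short-gap
merging, minimum duration, terminal flag) directly from their definitions.
It is deliberately naive and shares no scanning code with
:func:`cathflow.flowstop.detect_flow_stops`; agreement between the two is a
validation check, not a tautology.
"""

from __future__ import annotations

from .flowstop import DetectorConfig, estimate_flowrate
from .profile_io import ProfileTrace


def naive_flow_stop_intervals(
    trace: ProfileTrace, cfg: DetectorConfig | None = None
) -> list[tuple[int, int, bool]]:
    """Episodes as (start index, last index, terminal) via per-sample scan."""
    cfg = cfg or DetectorConfig()
    q = estimate_flowrate(trace, cfg)
    t = trace.t
    n = len(t)
    above = [float(q[i]) >= cfg.flow_threshold for i in range(n)]

    if True not in above:
        return [(0, n - 1, True)]
    onset = above.index(True)

    # maximal sub-threshold runs at or after flow onset
    runs: list[list[int]] = []
    i = onset
    while i < n:
        if not above[i]:
            j = i
            while j + 1 < n and not above[j + 1]:
                j += 1
            runs.append([i, j])
            i = j + 1
        else:
            i += 1

    # merge runs separated by an above-threshold gap shorter than merge_gap
    merged: list[list[int]] = []
    for run in runs:
        if merged:
            prev = merged[-1]
            prev_end_time = t[prev[1] + 1] if prev[1] + 1 < n else t[n - 1]
            if t[run[0]] - prev_end_time < cfg.merge_gap:
                prev[1] = run[1]
                continue
        merged.append(list(run))

    # minimum-duration rule (intervals closed left, open right)
    kept = []
    for i0, i1 in merged:
        end_time = t[i1 + 1] if i1 + 1 < n else t[n - 1]
        if end_time - t[i0] >= cfg.min_duration:
            kept.append((i0, i1))

    return [
        (i0, i1, k == len(kept) - 1) for k, (i0, i1) in enumerate(kept)
    ]
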