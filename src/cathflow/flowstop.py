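"""Flowrate estimation, flow-stop detection, and per-catheterisation endpoints.

A flow-stop is the signature of mucosal suction: drainage flowrate drops
below 0.8 mL/s for at least two seconds while the intra-catheter pressure
spikes negative.  Flowrate is estimated from the cumulative-volume trace by
a local least-squares slope (a centred window of +/-0.6 s, about three
samples at 2.5 Hz) rather than raw first differences, which would cross the
threshold spuriously under scale noise.

Conventions:

* Detection of non-terminal episodes starts at flow onset (first sample with
  flowrate at or above the threshold), so pre-drainage dead time is not a
  spurious leading flow-stop.
* Sub-threshold runs separated by above-threshold gaps shorter than
  ``merge_gap`` are merged before the minimum-duration rule is applied; this
  replaces the manual-inspection step of the clinical workflow with a
  deterministic rule.
* The last episode marks the end of catheterisation and is flagged
  ``terminal``; it is discounted from the flow-stop count, so a trace with a
  single episode has zero flow-stops.
* Episode intervals are closed on the left and open on the right.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .clinical_measures import classify_dipstick, summarize_scan
from .errors import DataError
from .profile_io import ClinicalRecord, ProfileTrace

#: pressure below which an episode is flagged as pressure-supported (cmH2O)
PRESSURE_SUPPORT_CMH2O = -5.0


@dataclass(frozen=True)
class DetectorConfig:
    """Tunable parameters of the flow-stop detector.

    flow_threshold and min_duration implement the clinical rule (flowrate
    < 0.8 mL/s for >= 2 s); the remaining fields are numerical choices of
    this implementation, exposed rather than hard-coded.
    """

    flow_threshold: float = 0.8   # mL/s
    min_duration: float = 2.0     # s
    smooth_halfwidth: float = 0.6  # s, half-width of the local-slope window
    merge_gap: float = 0.4        # s, above-threshold gaps shorter than this merge
    pressure_window_pad: float = 1.0  # s, padding of the suction-pressure window

    def __post_init__(self) -> None:
        if self.flow_threshold <= 0 or self.min_duration <= 0:
            raise DataError("flow_threshold and min_duration must be positive")
        if self.smooth_halfwidth <= 0:
            raise DataError("smooth_halfwidth must be positive")


@dataclass(frozen=True)
class FlowStopEpisode:
    """One detected sub-threshold flow interval [t_start, t_end)."""

    t_start: float
    t_end: float
    v_at_onset: float      # cumulative volume at t_start (mL)
    min_flowrate: float    # mL/s within the episode
    peak_suction: float    # most negative pressure in the padded window (cmH2O)
    terminal: bool
    pressure_supported: bool = field(default=False)

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start


@dataclass(frozen=True)
class CatheterisationEndpoints:
    """Derived per-catheterisation outcomes."""

    subject_id: str
    device: str
    visit: int
    v_total: float             # total catheterised volume (mL)
    v_first_stop: float        # cumulative volume at onset of the first episode (mL)
    rv1: float                 # residual urine at the first flow-stop (mL)
    n_flow_stops: int          # episodes excluding the terminal one
    peak_suction_first: float  # cmH2O
    haematuria_positive: bool | None = None
    postvoid_residual: float | None = None


def estimate_flowrate(trace: ProfileTrace, cfg: DetectorConfig | None = None) -> np.ndarray:
    """Flowrate (mL/s) on the trace's own grid, clipped below at zero.

    The flowrate at sample i is the slope of an ordinary least-squares line
    fitted to cumulative volume over timestamps within
    [t_i - smooth_halfwidth, t_i + smooth_halfwidth].
    """
    cfg = cfg or DetectorConfig()
    t, v = trace.t, trace.v
    h = cfg.smooth_halfwidth
    if trace.duration < 2 * h:
        raise DataError(
            f"trace duration {trace.duration:.2f} s shorter than the "
            f"smoothing window ({2 * h:.2f} s)"
        )
    lo = np.searchsorted(t, t - h, side="left")
    hi = np.searchsorted(t, t + h, side="right")  # exclusive
    n = hi - lo
    if np.any(n < 2):
        raise DataError("smoothing window contains fewer than 2 samples")
    # windowed OLS slope via prefix sums; centring reduces cancellation
    t = t - t.mean()
    v = v - v.mean()
    c1 = np.concatenate(([0.0], np.cumsum(t)))
    c2 = np.concatenate(([0.0], np.cumsum(t * t)))
    cv = np.concatenate(([0.0], np.cumsum(v)))
    ctv = np.concatenate(([0.0], np.cumsum(t * v)))
    st = c1[hi] - c1[lo]
    stt = c2[hi] - c2[lo]
    sv = cv[hi] - cv[lo]
    stv = ctv[hi] - ctv[lo]
    denom = n * stt - st * st
    with np.errstate(invalid="ignore", divide="ignore"):
        slope = np.where(denom > 0, (n * stv - st * sv) / denom, 0.0)
    return np.clip(slope, 0.0, None)


def _runs_below(below: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as (start, stop) index pairs, stop inclusive."""
    idx = np.flatnonzero(below)
    if idx.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate(([idx[0]], idx[breaks + 1]))
    stops = np.concatenate((idx[breaks], [idx[-1]]))
    return list(zip(starts.tolist(), stops.tolist()))


def _episode_from_run(
    trace: ProfileTrace, q: np.ndarray, i0: int, i1: int, cfg: DetectorConfig, terminal: bool
) -> FlowStopEpisode:
    t = trace.t
    # closed-left / open-right: the episode ends where flow resumes
    t_end = t[i1 + 1] if i1 + 1 < len(t) else t[-1]
    sel = (t >= t[i0] - cfg.pressure_window_pad) & (t < t_end + cfg.pressure_window_pad)
    peak = float(min(trace.p[sel].min(), 0.0))
    return FlowStopEpisode(
        t_start=float(t[i0]),
        t_end=float(t_end),
        v_at_onset=float(trace.v[i0]),
        min_flowrate=float(q[i0 : i1 + 1].min()),
        peak_suction=peak,
        terminal=terminal,
        pressure_supported=peak < PRESSURE_SUPPORT_CMH2O,
    )


def detect_flow_stops(
    trace: ProfileTrace, cfg: DetectorConfig | None = None
) -> list[FlowStopEpisode]:
    """Detect flow-stop episodes in one trace.

    Returns time-ordered, disjoint episodes; the last one is flagged
    terminal.  If the flowrate never reaches the threshold (no flow onset),
    the whole trace is returned as a single terminal episode.
    """
    cfg = cfg or DetectorConfig()
    q = estimate_flowrate(trace, cfg)
    t = trace.t
    above = q >= cfg.flow_threshold
    if not above.any():
        # no flow onset: the entire trace is one terminal stop
        sel = np.ones_like(t, dtype=bool)
        peak = float(min(trace.p[sel].min(), 0.0))
        return [
            FlowStopEpisode(
                t_start=float(t[0]),
                t_end=float(t[-1]),
                v_at_onset=float(trace.v[0]),
                min_flowrate=float(q.min()),
                peak_suction=peak,
                terminal=True,
                pressure_supported=peak < PRESSURE_SUPPORT_CMH2O,
            )
        ]
    onset = int(np.argmax(above))
    below = ~above
    below[:onset] = False
    runs = _runs_below(below)
    # merge runs separated by short above-threshold gaps
    merged: list[tuple[int, int]] = []
    for i0, i1 in runs:
        if merged:
            p0, p1 = merged[-1]
            gap_start = t[p1 + 1] if p1 + 1 < len(t) else t[-1]
            if t[i0] - gap_start < cfg.merge_gap:
                merged[-1] = (p0, i1)
                continue
        merged.append((i0, i1))
    # minimum-duration rule on the merged runs
    kept = []
    for i0, i1 in merged:
        t_end = t[i1 + 1] if i1 + 1 < len(t) else t[-1]
        if t_end - t[i0] >= cfg.min_duration:
            kept.append((i0, i1))
    return [
        _episode_from_run(trace, q, i0, i1, cfg, terminal=(k == len(kept) - 1))
        for k, (i0, i1) in enumerate(kept)
    ]


def count_flow_stops(episodes: Sequence[FlowStopEpisode]) -> int:
    """Number of non-terminal episodes (the terminal stop is discounted)."""
    return sum(1 for e in episodes if not e.terminal)


def derive_endpoints(
    trace: ProfileTrace,
    episodes: Sequence[FlowStopEpisode],
    record: ClinicalRecord | None = None,
) -> CatheterisationEndpoints:
    """Per-catheterisation endpoints from detected episodes.

    RV1 (residual urine at the first flow-stop) is the total catheterised
    volume minus the cumulative volume at onset of the first episode; the
    first episode may be the terminal one, which is why catheterisations
    with zero counted flow-stops still have positive RV1.
    """
    if not episodes:
        raise DataError("derive_endpoints needs at least one (terminal) episode")
    first = episodes[0]
    v_total = trace.v_total
    rv1 = v_total - first.v_at_onset
    haem: bool | None = None
    pvr: float | None = None
    if record is not None:
        haem = classify_dipstick(record.dipstick)
        pvr = summarize_scan(record.postvoid_scan).mean_volume
    return CatheterisationEndpoints(
        subject_id=trace.subject_id,
        device=trace.device,
        visit=trace.visit,
        v_total=v_total,
        v_first_stop=float(first.v_at_onset),
        rv1=float(rv1),
        n_flow_stops=count_flow_stops(episodes),
        peak_suction_first=float(first.peak_suction),
        haematuria_positive=haem,
        postvoid_residual=pvr,
    )
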