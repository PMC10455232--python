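"""Synthetic catheterisation traces and block-randomised crossover trials.

Two generators, layered:

``simulate_profile``
    Renders one catheterisation as a phenomenological pressure-volume trace:
    a flow ramp-up, a plateau that decays as the bladder empties, zero or
    more injected mucosal-suction events (flow falls to zero, pressure
    spikes negative), terminal flow cessation, and a slow post-terminal
    dribble.  Measurement noise is added to the cumulative mass, and the
    injected event times/volumes are returned as ground truth so the
    detector can be tested against a known answer.

``simulate_trial``
    Draws a whole two-visit crossover trial at the endpoint level: AB/BA
    sequences assigned in blocks of four, and per-catheterisation endpoints
    generated from random-intercept models (Gaussian for continuous
    endpoints, Poisson log-link for flow-stop counts, Bernoulli logit-link
    for haematuria).  ``simulate_trial_with_traces`` additionally renders a
    trace per catheterisation whose ground truth matches the recorded
    endpoint values, so the full measurement-to-inference chain can be run
    end to end.

Default calibration is synthetic: event rates, residual-volume
distributions, and suction-amplitude distributions are chosen so that the
derived endpoints resemble the device-level summaries reported for a
micro-hole zone catheter (MHZC) versus a conventional eyelet catheter
(CEC), with lognormal amplitudes truncated at the observed per-device
pressure extremes.  These defaults emulate plausible study conditions; they
are not estimates of any real catheter's physics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ConfigError
from .profile_io import ClinicalRecord, ProfileTrace, repair_monotone

# dipstick categories used when rendering a positive / negative assessment
_POSITIVE_CATEGORIES = (
    "haemolysed 25 (1+)",
    "haemolysed 80 (2+)",
    "non-haemolysed 80 (2+)",
    "haemolysed 200 (3+)",
)
_NEGATIVE_CATEGORIES = (
    "negative",
    "non-haemolysed 10 (+/-)",
    "haemolysed 10 (+/-)",
)


@dataclass(frozen=True)
class DeviceProfileParams:
    """Per-device marginal calibration of the trace generator."""

    event_rate: float            # Poisson mean of non-terminal suction events
    rv1_log_mu: float            # lognormal location of residual volume at first stop
    rv1_log_sd: float            # lognormal scale
    amp_log_median: float        # cmH2O, median suction amplitude
    amp_log_sd: float
    amp_truncation: float        # cmH2O, amplitudes truncated at this magnitude


#: defaults emulating the two devices' endpoint summaries (synthetic calibration)
DEVICE_PARAMS: dict[str, DeviceProfileParams] = {
    "MHZC": DeviceProfileParams(
        event_rate=0.17,
        rv1_log_mu=math.log(5.1) - 0.75**2 / 2,
        rv1_log_sd=0.75,
        amp_log_median=14.0,
        amp_log_sd=0.6,
        amp_truncation=87.7,
    ),
    "CEC": DeviceProfileParams(
        event_rate=1.09,
        rv1_log_mu=math.log(39.4) - 1.4**2 / 2,
        rv1_log_sd=1.4,
        amp_log_median=95.0,
        amp_log_sd=0.6,
        amp_truncation=423.2,
    ),
}


@dataclass(frozen=True)
class ProfileSimConfig:
    """Trace-generator settings shared across devices."""

    bladder_volume: tuple[float, float] = (150.0, 500.0)  # mL, uniform draw
    plateau_flow: tuple[float, float] = (2.5, 5.5)        # mL/s, uniform draw
    flow_decay: float = 0.3        # shape of the late-drainage flow decline
    flow_floor: float = 1.2        # mL/s, active flow never drops below this
    ramp_duration: float = 2.5     # s, initial flow ramp-up
    suction_duration: tuple[float, float] = (3.5, 8.0)    # s, uniform draw
    dribble_rate_bounds: tuple[float, float] = (0.12, 0.40)  # mL/s trickle
    postvoid_residual_mean: float = 6.5   # mL (true residual left in bladder)
    postvoid_residual_sd: float = 3.0
    mass_noise_sd: float = 0.05    # g, precision-scale noise on cumulative mass
    pressure_noise_sd: float = 0.5  # cmH2O
    sampling_rate: float = 2.5     # Hz
    tail_duration: float = 4.5     # s of zero flow recorded after the dribble ends
    device_params: Mapping[str, DeviceProfileParams] = field(
        default_factory=lambda: dict(DEVICE_PARAMS)
    )

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise ConfigError("sampling_rate must be positive")
        if self.bladder_volume[0] < 150.0:
            raise ConfigError("bladder_volume lower bound below the 150 mL eligibility floor")
        if self.bladder_volume[0] > self.bladder_volume[1]:
            raise ConfigError("bladder_volume bounds out of order")


@dataclass(frozen=True)
class InjectedEvent:
    """Ground truth for one injected suction event."""

    t_start: float
    duration: float
    amplitude: float   # cmH2O magnitude (positive number)
    v_at_onset: float  # true cumulative volume when flow stopped


@dataclass(frozen=True)
class ProfileGroundTruth:
    """True injected quantities behind one simulated trace."""

    device: str
    v_total: float
    n_flow_stops: int                 # injected non-terminal events
    rv1: float                        # v_total minus volume at the first stop
    v_first_stop: float
    events: tuple[InjectedEvent, ...]
    terminal_onset_t: float
    terminal_v_at_onset: float
    dribble_volume: float
    terminal_amplitude: float
    postvoid_residual: float


def _truncated_lognormal(rng, median: float, log_sd: float, upper: float) -> float:
    x = median * math.exp(log_sd * rng.standard_normal())
    return min(x, upper)


# volume margins (mL) keeping injected events resolvable by the detector:
# a first stop needs at least _GAP_ML of active drainage before the terminal
# dribble, and successive events need _EVENT_SPACING_ML between onsets.
_GAP_ML = 2.0
_EVENT_SPACING_ML = 3.0
_FIRST_TRIGGER_MIN_ML = 12.0


def simulate_profile(
    cfg: ProfileSimConfig,
    device: str,
    rng: np.random.Generator,
    targets: Mapping[str, float] | None = None,
) -> tuple[ProfileTrace, ProfileGroundTruth]:
    """Render one catheterisation trace plus its ground truth.

    ``targets`` may pin per-trace draws (keys ``n_flow_stops``, ``rv1``,
    ``v_total``, ``plateau_flow``); anything not pinned is drawn from the
    device's marginal calibration.  Targets that are geometrically
    infeasible (e.g. a first stop closer to the terminal dribble than the
    detector could resolve) are adjusted minimally; the returned ground
    truth always reflects what was actually injected.
    """
    if device not in cfg.device_params:
        raise ConfigError(f"no device parameters for {device!r}")
    par = cfg.device_params[device]
    targets = dict(targets or {})

    pvr = max(0.0, rng.normal(cfg.postvoid_residual_mean, cfg.postvoid_residual_sd))
    if "v_total" in targets:
        v_total = float(targets["v_total"])
    else:
        v_total = rng.uniform(*cfg.bladder_volume) - pvr
    v_total = max(v_total, 120.0)
    q0 = float(targets.get("plateau_flow", rng.uniform(*cfg.plateau_flow)))

    n_events = int(targets.get("n_flow_stops", rng.poisson(par.event_rate)))
    rv1 = float(
        targets.get("rv1", math.exp(par.rv1_log_mu + par.rv1_log_sd * rng.standard_normal()))
    )
    rv1 = min(rv1, 0.6 * v_total)

    if n_events == 0:
        dribble = float(np.clip(rv1, 0.5, 0.5 * v_total))
    else:
        dribble = rng.uniform(0.6, 1.2)
        # keep the first stop resolvable ahead of the terminal dribble
        min_rv1 = dribble + _GAP_ML + _EVENT_SPACING_ML * (n_events - 1)
        rv1 = max(rv1, min_rv1)
        rv1 = min(rv1, v_total - _FIRST_TRIGGER_MIN_ML)

    v_terminal = v_total - dribble
    durations = [rng.uniform(*cfg.suction_duration) for _ in range(n_events)]
    amplitudes = [
        _truncated_lognormal(rng, par.amp_log_median, par.amp_log_sd, par.amp_truncation)
        for _ in range(n_events)
    ]
    terminal_amp = _truncated_lognormal(
        rng, par.amp_log_median, par.amp_log_sd, par.amp_truncation
    )

    # event trigger volumes: first fixed by the rv1 target, later ones spread
    # over the span left before terminal onset
    triggers: list[float] = []
    if n_events:
        first = v_total - rv1
        triggers.append(first)
        lo = first
        for k in range(1, n_events):
            remaining_events = n_events - k
            hi = v_terminal - _GAP_ML - _EVENT_SPACING_ML * (remaining_events - 1)
            lo = lo + _EVENT_SPACING_ML
            nxt = rng.uniform(lo, hi) if hi > lo else lo
            triggers.append(nxt)
            lo = nxt

    dt = 1.0 / cfg.sampling_rate
    dribble_rate = float(np.clip(dribble / 45.0, *cfg.dribble_rate_bounds))

    t_list: list[float] = []
    v_list: list[float] = []
    well: list[float] = []  # deterministic suction-well pressure (<= 0)

    t = 0.0
    drained = 0.0
    event_idx = 0
    event_end = -1.0
    event_amp = 0.0
    events_out: list[InjectedEvent] = []
    terminal_onset_t = None
    terminal_v = None
    tail_left = cfg.tail_duration
    max_samples = 100_000

    while len(t_list) < max_samples:
        in_event = t < event_end
        if in_event:
            q = 0.0
        elif drained >= v_terminal - 1e-9:
            if terminal_onset_t is None:
                terminal_onset_t = t
                terminal_v = drained
            if drained < v_total - 1e-9:
                q = min(dribble_rate, (v_total - drained) / dt)
            else:
                q = 0.0
        else:
            ramp = min(1.0, t / cfg.ramp_duration) if cfg.ramp_duration > 0 else 1.0
            frac = max(0.0, (v_terminal - drained) / max(v_terminal, 1e-9))
            q = ramp * max(cfg.flow_floor, q0 * frac**cfg.flow_decay)
            if event_idx < len(triggers) and drained >= triggers[event_idx]:
                # suction event begins at this sample
                event_end = t + durations[event_idx]
                event_amp = amplitudes[event_idx]
                events_out.append(
                    InjectedEvent(
                        t_start=t,
                        duration=durations[event_idx],
                        amplitude=event_amp,
                        v_at_onset=drained,
                    )
                )
                event_idx += 1
                q = 0.0
                in_event = True

        # suction well: active during events and from terminal onset onwards
        w = 0.0
        if in_event:
            edge = min(t - events_out[-1].t_start, max(event_end - t, 0.0), 0.6) / 0.6
            w = -event_amp * min(1.0, edge + 1e-9) if edge > 0 else -event_amp * 0.1
        elif terminal_onset_t is not None:
            edge = min((t - terminal_onset_t) / 0.6, 1.0)
            w = -terminal_amp * max(edge, 0.05)

        t_list.append(t)
        v_list.append(drained)
        well.append(w)

        if terminal_onset_t is not None and drained >= v_total - 1e-9:
            tail_left -= dt
            if tail_left <= 0:
                break
        drained = min(v_total, drained + q * dt)
        t += dt

    t_arr = np.asarray(t_list)
    v_true = np.asarray(v_list)
    noise = rng.normal(0.0, cfg.mass_noise_sd, size=v_true.shape)
    v_meas, _ = repair_monotone(np.clip(v_true + noise, 0.0, None))
    p = np.asarray(well) + rng.normal(0.0, cfg.pressure_noise_sd, size=v_true.shape)
    p = np.clip(p, -par.amp_truncation, 0.0)

    if events_out:
        v_first = events_out[0].v_at_onset
    else:
        v_first = float(terminal_v)
    truth = ProfileGroundTruth(
        device=device,
        v_total=float(v_true[-1]),
        n_flow_stops=len(events_out),
        rv1=float(v_true[-1] - v_first),
        v_first_stop=float(v_first),
        events=tuple(events_out),
        terminal_onset_t=float(terminal_onset_t),
        terminal_v_at_onset=float(terminal_v),
        dribble_volume=dribble,
        terminal_amplitude=terminal_amp,
        postvoid_residual=pvr,
    )
    trace = ProfileTrace(
        subject_id=str(targets.get("subject_id", "sim")),
        device=device,
        visit=int(targets.get("visit", 1)),
        t=t_arr,
        v=v_meas,
        p=p,
        sampling_rate_nominal=cfg.sampling_rate,
    )
    return trace, truth


# ---------------------------------------------------------------------------
# trial-level generator


@dataclass(frozen=True)
class EndpointModel:
    """One endpoint's generating model on its link scale.

    ``mu`` is the comparator (CEC) visit-1 level, ``device_effect`` the
    MHZC-minus-CEC shift (identity scale for gaussian, log rate ratio for
    poisson, log odds ratio for bernoulli).
    """

    name: str
    family: str  # gaussian | poisson | bernoulli
    mu: float
    device_effect: float
    visit_effect: float = 0.0
    sigma_subject: float = 0.0
    sigma_resid: float = 0.0

    def __post_init__(self) -> None:
        if self.family not in ("gaussian", "poisson", "bernoulli"):
            raise ConfigError(f"unknown endpoint family {self.family!r}")
        if self.sigma_subject < 0 or self.sigma_resid < 0:
            raise ConfigError("endpoint SDs must be non-negative")


def _logit(p: float) -> float:
    return math.log(p / (1 - p))


#: default endpoint models, calibrated so device-level summaries resemble the
#: published performance table (synthetic calibration, not estimates)
DEFAULT_ENDPOINTS: tuple[EndpointModel, ...] = (
    EndpointModel("rv1", "gaussian", mu=39.4, device_effect=-34.3,
                  sigma_subject=20.0, sigma_resid=45.8),
    EndpointModel("n_flow_stops", "poisson", mu=math.log(1.09),
                  device_effect=math.log(0.16), sigma_subject=0.6),
    EndpointModel("haematuria", "bernoulli", mu=_logit(0.29),
                  device_effect=math.log(0.26), sigma_subject=1.0),
    EndpointModel("postvoid_residual", "gaussian", mu=7.13, device_effect=-1.21,
                  sigma_subject=10.0, sigma_resid=28.0),
    EndpointModel("peak_suction", "gaussian", mu=-113.0, device_effect=96.5,
                  sigma_subject=40.0, sigma_resid=96.0),
)


@dataclass(frozen=True)
class TrialSimConfig:
    """Crossover-trial generator settings."""

    n_subjects: int = 42
    endpoints: tuple[EndpointModel, ...] = DEFAULT_ENDPOINTS
    dropout_rate: float = 1.0 / 42.0  # probability a subject misses visit 2
    block_size: int = 4
    neurogenic_fraction: float = 13.0 / 42.0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ConfigError("need at least 2 subjects")
        if self.block_size % 2:
            raise ConfigError("block_size must be even to balance sequences")
        if not (0 <= self.dropout_rate < 1):
            raise ConfigError("dropout_rate must be in [0, 1)")


def assign_sequences(n_subjects: int, block_size: int, rng: np.random.Generator) -> list[str]:
    """Block-randomised AB/BA assignment ('MHZC-first' / 'CEC-first')."""
    seqs: list[str] = []
    while len(seqs) < n_subjects:
        block = ["MHZC-first"] * (block_size // 2) + ["CEC-first"] * (block_size // 2)
        rng.shuffle(block)
        seqs.extend(block)
    return seqs[:n_subjects]


def simulate_trial(
    cfg: TrialSimConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Draw one crossover trial at the endpoint level.

    Returns a long-format frame with one row per catheterisation: columns
    ``subject, sequence, visit, device, medical_history`` plus one column
    per configured endpoint.  Subjects lost to dropout contribute only
    their visit-1 row.
    """
    sequences = assign_sequences(cfg.n_subjects, cfg.block_size, rng)
    intercepts = {
        ep.name: rng.normal(0.0, ep.sigma_subject, size=cfg.n_subjects)
        for ep in cfg.endpoints
    }
    histories = np.where(
        rng.random(cfg.n_subjects) < cfg.neurogenic_fraction, "neurogenic", "non-neurogenic"
    )
    dropout = rng.random(cfg.n_subjects) < cfg.dropout_rate

    rows = []
    for i in range(cfg.n_subjects):
        first = "MHZC" if sequences[i] == "MHZC-first" else "CEC"
        second = "CEC" if first == "MHZC" else "MHZC"
        for visit, device in ((1, first), (2, second)):
            if visit == 2 and dropout[i]:
                continue
            row: dict[str, object] = {
                "subject": f"S{i + 1:03d}",
                "sequence": sequences[i],
                "visit": visit,
                "device": device,
                "medical_history": histories[i],
            }
            for ep in cfg.endpoints:
                eta = (
                    ep.mu
                    + (ep.device_effect if device == "MHZC" else 0.0)
                    + (ep.visit_effect if visit == 2 else 0.0)
                    + intercepts[ep.name][i]
                )
                if ep.family == "gaussian":
                    val: object = eta + rng.normal(0.0, ep.sigma_resid)
                elif ep.family == "poisson":
                    val = int(rng.poisson(math.exp(eta)))
                else:
                    val = bool(rng.random() < 1.0 / (1.0 + math.exp(-eta)))
                row[ep.name] = val
            rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class TrialSimOutput:
    """A fully rendered trial: endpoint table, traces, records, ground truth."""

    dataset: pd.DataFrame
    traces: list[ProfileTrace]
    records: list[ClinicalRecord]
    ground_truths: list[ProfileGroundTruth]


def simulate_trial_with_traces(
    trial_cfg: TrialSimConfig,
    profile_cfg: ProfileSimConfig,
    rng: np.random.Generator,
    subject_frailty_sd: float = 0.4,
) -> TrialSimOutput:
    """Render a whole trial down to the trace level.

    Per-catheterisation flow-stop counts and residual-volume targets are
    drawn from the device marginals with a shared per-subject lognormal
    frailty, a trace is rendered for each, and the endpoint table records
    the trace ground truth (so dataset and traces are mutually consistent).
    """
    sequences = assign_sequences(trial_cfg.n_subjects, trial_cfg.block_size, rng)
    frailty = rng.normal(0.0, subject_frailty_sd, size=trial_cfg.n_subjects)
    histories = np.where(
        rng.random(trial_cfg.n_subjects) < trial_cfg.neurogenic_fraction,
        "neurogenic",
        "non-neurogenic",
    )
    dropout = rng.random(trial_cfg.n_subjects) < trial_cfg.dropout_rate
    haem_model = next(
        (ep for ep in trial_cfg.endpoints if ep.name == "haematuria"), None
    )

    rows, traces, records, truths = [], [], [], []
    for i in range(trial_cfg.n_subjects):
        first = "MHZC" if sequences[i] == "MHZC-first" else "CEC"
        second = "CEC" if first == "MHZC" else "MHZC"
        sid = f"S{i + 1:03d}"
        for visit, device in ((1, first), (2, second)):
            if visit == 2 and dropout[i]:
                continue
            par = profile_cfg.device_params[device]
            count = int(rng.poisson(par.event_rate * math.exp(frailty[i])))
            rv1 = math.exp(
                par.rv1_log_mu + frailty[i] + par.rv1_log_sd * rng.standard_normal()
            )
            trace, truth = simulate_profile(
                profile_cfg,
                device,
                rng,
                targets={
                    "n_flow_stops": count,
                    "rv1": rv1,
                    "subject_id": sid,
                    "visit": visit,
                },
            )
            if haem_model is not None:
                eta = (
                    haem_model.mu
                    + (haem_model.device_effect if device == "MHZC" else 0.0)
                    + haem_model.sigma_subject * frailty[i] / max(subject_frailty_sd, 1e-9)
                )
                positive = rng.random() < 1.0 / (1.0 + math.exp(-eta))
            else:
                positive = False
            cats = _POSITIVE_CATEGORIES if positive else _NEGATIVE_CATEGORIES
            dip = cats[rng.integers(len(cats))]
            prevoid = truth.v_total + truth.postvoid_residual
            record = ClinicalRecord(
                subject_id=sid,
                visit=visit,
                device=device,
                prevoid_scan=tuple(
                    max(150.0, prevoid + rng.normal(0, 8.0)) for _ in range(3)
                ),
                postvoid_scan=tuple(
                    max(0.0, truth.postvoid_residual + rng.normal(0, 4.0))
                    for _ in range(3)
                ),
                dipstick=dip,
                medical_history=str(histories[i]),
            )
            rows.append(
                {
                    "subject": sid,
                    "sequence": sequences[i],
                    "visit": visit,
                    "device": device,
                    "medical_history": str(histories[i]),
                    "rv1": truth.rv1,
                    "n_flow_stops": truth.n_flow_stops,
                    "haematuria": positive,
                    "postvoid_residual": truth.postvoid_residual,
                    "peak_suction": -(
                        truth.events[0].amplitude if truth.events else truth.terminal_amplitude
                    ),
                }
            )
            traces.append(trace)
            records.append(record)
            truths.append(truth)
    return TrialSimOutput(pd.DataFrame(rows), traces, records, truths)
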