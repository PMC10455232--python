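import numpy as np
import pytest

from cathflow.profile_io import ProfileTrace


def trace_from_flow(segments, dt=0.4, subject="T", device="CEC", visit=1, pressure=None):
    """Build a trace from piecewise-constant flow segments [(n_samples, mL/s), ...]."""
    q = np.concatenate([np.full(n, rate, dtype=float) for n, rate in segments])
    t = np.arange(len(q)) * dt
    v = np.concatenate(([0.0], np.cumsum(q[:-1] * dt)))
    p = np.zeros_like(t) if pressure is None else np.asarray(pressure, float)
    return ProfileTrace(subject_id=subject, device=device, visit=visit, t=t, v=v, p=p)


@pytest.fixture
def flow_trace():
    return trace_from_flow


@pytest.fixture
def rng():
    return np.random.default_rng(20230813)


@pytest.fixture(scope="session")
def sim_corpus():
    """A reusable seeded corpus of simulated traces with ground truth."""
    from cathflow.synth import ProfileSimConfig, simulate_profile

    gen = np.random.default_rng(42)
    cfg = ProfileSimConfig()
    corpus = []
    for i in range(120):
        device = "MHZC" if i % 2 else "CEC"
        corpus.append(simulate_profile(cfg, device, gen))
    return corpus
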