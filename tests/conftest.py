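"""Shared fixtures: small protocols and hand-built sessions."""

import numpy as np
import pytest

from blinklearn import Session, SessionStage, StimulusProtocol, Trial, TrialKind


@pytest.fixture
def protocol():
    return StimulusProtocol()


@pytest.fixture
def small_protocol():
    """Default timing but a light 500 Hz EMG grid (1500 samples/trial)."""
    return StimulusProtocol(emg_rate_hz=500.0)


def build_session(
    protocol,
    spike_lists,
    kinds=None,
    stage=SessionStage.initial,
    units=None,
    emg=None,
):
    """Hand-build a session from per-trial {unit: times} dicts."""
    n_trials = len(spike_lists)
    if kinds is None:
        kinds = [TrialKind.paired] * n_trials
    if units is None:
        units = sorted({u for d in spike_lists for u in d})
    n = protocol.n_emg_samples
    trials = []
    for i, (spikes, kind) in enumerate(zip(spike_lists, kinds)):
        trace = np.zeros(n) if emg is None else np.asarray(emg[i], dtype=float)
        trials.append(
            Trial(
                trial_id=i,
                kind=kind,
                emg=trace,
                spikes={u: np.asarray(t, dtype=float) for u, t in spikes.items()},
            )
        )
    return Session(stage=stage, protocol=protocol, trials=trials, units=list(units))


@pytest.fixture
def session_builder():
    return build_session
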