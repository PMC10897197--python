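"""Synthetic eyeblink-conditioning sessions.

Spike trains are drawn from an inhomogeneous Poisson process via
Lewis-Shedler thinning with an absolute refractory dead time. The firing
rate of a unit on a trial is a piecewise profile

    lambda(t) = g_u * baseline * [1 + cs_gain * 1(CS on)
                                    + us_gain * 1(US on; paired only)
                                    + ramp(t)
                                    + late(t; paired only)]

where ``ramp(t)`` rises linearly from 0 at ``ramp_onset_s`` to ``ramp_gain``
at US onset and stays at ``ramp_gain`` until US offset (the learned,
predictive component, present on CS-alone trials too), and
``late(t) = late_error_gain * exp(-(t - us_offset)/late_error_tau_s)`` for
t >= US offset models the long-lasting post-US error response of
unconditioned animals (driven by the US, hence paired trials only).
``g_u`` is a per-unit lognormal gain capturing the wide firing-rate range of
real deep-cerebellar units.

EMG traces are zero-mean Gaussian noise plus rectangular-windowed bursts of
amplitude-modulated noise: every paired trial carries an unconditioned
reflex burst (UR) just after US onset, and any trial carries, with
probability ``cr_prob``, a conditioned-response burst (CR) whose onset is
drawn from a truncated normal on [50 ms, US onset).

The stage presets (initial / halfway / final) reproduce the qualitative
learning trajectory: high baseline and a large late error response before
learning; a reduced error response and a small predictive ramp halfway; a
low baseline, a dominant predictive ramp, no US-evoked extra burst, and a
high CR incidence once conditioning is established.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .session import Session, SessionStage, StimulusProtocol, Trial, TrialKind

__all__ = [
    "StageRateProfile",
    "EmgGenConfig",
    "GeneratorConfig",
    "RateFunction",
    "rate_function",
    "simulate_spike_train",
    "simulate_emg_trial",
    "EmgTrialInfo",
    "generate_session",
    "STAGE_PRESETS",
    "default_config",
]

# Stream tags for counter-based rng splitting (spawn keys of the master seed).
_STREAM_SPIKES = 0
_STREAM_EMG = 1
_STREAM_LAYOUT = 2
_STREAM_UNIT_GAIN = 3

_STAGE_INDEX = {SessionStage.initial: 0, SessionStage.halfway: 1, SessionStage.final: 2}


@dataclass(frozen=True)
class StageRateProfile:
    """Rate-profile parameters of one learning stage (gains are unitless)."""

    baseline_hz: float = 10.0
    cs_gain: float = 0.0
    us_gain: float = 0.0
    late_error_gain: float = 0.0
    late_error_tau_s: float = 0.4
    ramp_onset_s: float = 0.1
    ramp_gain: float = 0.0
    refractory_s: float = 0.002

    def validate(self, protocol: StimulusProtocol) -> None:
        if self.baseline_hz <= 0:
            raise ValueError("baseline_hz must be positive")
        if min(self.cs_gain, self.us_gain, self.late_error_gain, self.ramp_gain) < 0:
            raise ValueError("gains must be nonnegative")
        if self.late_error_tau_s <= 0:
            raise ValueError("late_error_tau_s must be positive")
        if not (0 <= self.ramp_onset_s < protocol.us_onset_s):
            raise ValueError("ramp_onset_s must lie in [0, us_onset_s)")
        if self.refractory_s < 0:
            raise ValueError("refractory_s must be nonnegative")


@dataclass(frozen=True)
class EmgGenConfig:
    """EMG generator parameters (amplitudes in arbitrary units)."""

    noise_sd: float = 1.0
    ur_latency_s: float = 0.010
    ur_amp: float = 8.0
    cr_prob: float = 0.0
    cr_latency_mean_s: float = 0.15
    cr_latency_sd_s: float = 0.03
    cr_amp: float = 5.0
    #: an orbicularis-oculi closing burst lasts a few hundred ms, so the
    #: conditioned burst merges into the reflex burst rather than preceding
    #: it as an isolated bump
    burst_duration_s: float = 0.200

    def validate(self, protocol: StimulusProtocol) -> None:
        if not 0 <= self.cr_prob <= 1:
            raise ValueError("cr_prob must lie in [0, 1]")
        if not 0.050 <= self.cr_latency_mean_s < protocol.us_onset_s:
            raise ValueError("cr_latency_mean_s must lie in [0.050, us_onset_s)")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")


#: Stage presets mirroring the learning trajectory (see module docstring).
#: Baselines follow the reported per-10 ms-bin spontaneous means
#: (0.0872 / 0.0778 / 0.0533 -> 8.7 / 7.8 / 5.3 Hz); gains are free
#: parameters chosen for the documented qualitative structure.
STAGE_PRESETS: dict[SessionStage, tuple[StageRateProfile, EmgGenConfig]] = {
    SessionStage.initial: (
        StageRateProfile(
            baseline_hz=8.7, cs_gain=0.0, us_gain=2.3,
            late_error_gain=3.0, late_error_tau_s=0.45,
            ramp_onset_s=0.13, ramp_gain=0.0,
        ),
        EmgGenConfig(cr_prob=0.07, cr_latency_mean_s=0.22, ur_amp=8.0),
    ),
    SessionStage.halfway: (
        StageRateProfile(
            baseline_hz=7.8, cs_gain=0.0, us_gain=1.9,
            late_error_gain=1.5, late_error_tau_s=0.40,
            ramp_onset_s=0.15, ramp_gain=0.8,
        ),
        EmgGenConfig(cr_prob=0.25, cr_latency_mean_s=0.18, ur_amp=6.0),
    ),
    SessionStage.final: (
        StageRateProfile(
            baseline_hz=5.3, cs_gain=0.0, us_gain=0.0,
            late_error_gain=1.5, late_error_tau_s=0.40,
            ramp_onset_s=0.04, ramp_gain=7.0,
        ),
        # the reflex burst shrinks once the conditioned closure already
        # shields the cornea when the puff arrives
        EmgGenConfig(cr_prob=0.81, cr_latency_mean_s=0.12, ur_amp=3.0),
    ),
}


@dataclass(frozen=True)
class GeneratorConfig:
    """Full configuration of a synthetic-session run."""

    protocol: StimulusProtocol = StimulusProtocol()
    rate_profiles: dict = field(
        default_factory=lambda: {s: p for s, (p, _) in STAGE_PRESETS.items()}
    )
    emg_configs: dict = field(
        default_factory=lambda: {s: e for s, (_, e) in STAGE_PRESETS.items()}
    )
    n_units: int = 20
    n_paired: int = 60
    n_cs_alone: int = 6
    unit_gain_sigma: float = 0.8
    seed: int = 0

    def validate(self) -> None:
        if self.n_units < 1:
            raise ValueError("n_units must be >= 1")
        if self.n_paired < 0 or self.n_cs_alone < 0:
            raise ValueError("trial counts must be nonnegative")
        if self.n_cs_alone > 0 and self.n_paired < 1:
            raise ValueError("cs_alone trials require at least one paired trial")


def default_config(**overrides) -> GeneratorConfig:
    """The study-condition configuration (stage presets, 60+6 trials)."""
    return replace(GeneratorConfig(), **overrides) if overrides else GeneratorConfig()


class RateFunction:
    """Vectorized firing-rate profile lambda(t) with analytic integrals."""

    def __init__(
        self,
        profile: StageRateProfile,
        protocol: StimulusProtocol,
        kind: TrialKind,
        gain: float = 1.0,
    ):
        profile.validate(protocol)
        self.profile = profile
        self.protocol = protocol
        self.kind = kind
        self.gain = gain
        self.paired = kind is TrialKind.paired

    @property
    def max_rate(self) -> float:
        p, base = self.profile, self.gain * self.profile.baseline_hz
        bound = 1.0 + p.cs_gain + p.ramp_gain
        if self.paired:
            bound += p.us_gain + p.late_error_gain
        return base * bound

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        p, proto = self.profile, self.protocol
        mult = np.ones_like(t)
        cs_on = (t >= proto.cs_onset_s) & (t < proto.cs_offset_s)
        mult += p.cs_gain * cs_on
        # predictive ramp: linear rise to the US onset, plateau through the US
        if p.ramp_gain > 0:
            rise = (t >= p.ramp_onset_s) & (t < proto.us_onset_s)
            denom = proto.us_onset_s - p.ramp_onset_s
            mult += np.where(rise, p.ramp_gain * (t - p.ramp_onset_s) / denom, 0.0)
            plateau = (t >= proto.us_onset_s) & (t < proto.us_offset_s)
            mult += p.ramp_gain * plateau
        if self.paired:
            us_on = (t >= proto.us_onset_s) & (t < proto.us_offset_s)
            mult += p.us_gain * us_on
            late = t >= proto.us_offset_s
            if p.late_error_gain > 0:
                mult += np.where(
                    late,
                    p.late_error_gain * np.exp(-(t - proto.us_offset_s) / p.late_error_tau_s),
                    0.0,
                )
        return self.gain * p.baseline_hz * mult

    def integral(self, a: float, b: float) -> float:
        """Exact integral of lambda over [a, b)."""
        if b <= a:
            return 0.0
        p, proto = self.profile, self.protocol

        def overlap(lo, hi):
            return max(0.0, min(b, hi) - max(a, lo))

        total = (b - a) + p.cs_gain * overlap(proto.cs_onset_s, proto.cs_offset_s)
        if p.ramp_gain > 0:
            lo, hi = max(a, p.ramp_onset_s), min(b, proto.us_onset_s)
            if hi > lo:
                denom = proto.us_onset_s - p.ramp_onset_s
                # integral of g*(t - t0)/d over [lo, hi)
                total += p.ramp_gain * ((hi - p.ramp_onset_s) ** 2 - (lo - p.ramp_onset_s) ** 2) / (
                    2 * denom
                )
            total += p.ramp_gain * overlap(proto.us_onset_s, proto.us_offset_s)
        if self.paired:
            total += p.us_gain * overlap(proto.us_onset_s, proto.us_offset_s)
            lo = max(a, proto.us_offset_s)
            if b > lo and p.late_error_gain > 0:
                tau = p.late_error_tau_s
                total += p.late_error_gain * tau * (
                    math.exp(-(lo - proto.us_offset_s) / tau)
                    - math.exp(-(b - proto.us_offset_s) / tau)
                )
        return self.gain * p.baseline_hz * total

    def mean_rate(self, a: float, b: float) -> float:
        """Average of lambda over the window [a, b), in Hz."""
        return self.integral(a, b) / (b - a)

    def dead_time_mean_rate(self, a: float, b: float, refractory_s: float | None = None) -> float:
        """Window-mean output rate after refractory (type-I dead time) attenuation.

        For a (locally) constant rate the thinned process fires at
        lambda / (1 + lambda * tau); the window mean applies this pointwise
        on a fine grid.
        """
        tau = self.profile.refractory_s if refractory_s is None else refractory_s
        t = np.linspace(a, b, 2001)
        lam = self(0.5 * (t[:-1] + t[1:]))
        return float(np.mean(lam / (1.0 + lam * tau)))


def rate_function(
    profile: StageRateProfile,
    protocol: StimulusProtocol,
    kind: TrialKind,
    gain: float = 1.0,
) -> RateFunction:
    """Build the piecewise rate profile for one trial kind."""
    return RateFunction(profile, protocol, kind, gain)


def simulate_spike_train(
    rate_fn,
    protocol: StimulusProtocol,
    refractory_s: float,
    rng: np.random.Generator,
    lam_max: float | None = None,
) -> np.ndarray:
    """One spike train by Lewis-Shedler thinning with a refractory dead time.

    ``rate_fn`` must be bounded by ``lam_max`` (taken from the function's
    ``max_rate`` attribute if not given). Spike times are rounded to
    microseconds, matching the on-disk precision.
    """
    if lam_max is None:
        lam_max = getattr(rate_fn, "max_rate")
    if lam_max <= 0:
        return np.empty(0, dtype=float)
    t0, t1 = protocol.epoch_start_s, protocol.epoch_end_s
    n_cand = rng.poisson(lam_max * (t1 - t0))
    if n_cand == 0:
        return np.empty(0, dtype=float)
    cand = np.sort(rng.uniform(t0, t1, size=n_cand))
    accept = rng.uniform(0.0, 1.0, size=n_cand) * lam_max < rate_fn(cand)
    cand = cand[accept]
    if refractory_s > 0 and cand.size > 1:
        kept = [cand[0]]
        last = cand[0]
        for t in cand[1:]:
            if t - last >= refractory_s:
                kept.append(t)
                last = t
        cand = np.asarray(kept)
    cand = np.round(cand, 6)
    if cand.size > 1:  # microsecond rounding may collapse near-coincident times
        cand = cand[np.concatenate(([True], np.diff(cand) > 0))]
    return cand


@dataclass(frozen=True)
class EmgTrialInfo:
    """Ground truth of one simulated EMG trial (for recovery tests)."""

    cr_present: bool
    cr_latency_s: float | None
    ur_onset_s: float | None


def simulate_emg_trial(
    cfg: EmgGenConfig,
    protocol: StimulusProtocol,
    kind: TrialKind,
    rng: np.random.Generator,
) -> tuple[np.ndarray, EmgTrialInfo]:
    """One raw EMG trace plus its ground truth.

    The trace is zero-mean Gaussian noise; bursts add independent noise of
    amplitude ``cr_amp`` / ``ur_amp`` under a rectangular envelope.
    """
    cfg.validate(protocol)
    n = protocol.n_emg_samples
    rate = protocol.emg_rate_hz
    trace = rng.normal(0.0, cfg.noise_sd, size=n)

    def add_burst(onset_s: float, amp: float) -> None:
        i0 = int(round((onset_s - protocol.epoch_start_s) * rate))
        i1 = min(n, i0 + int(round(cfg.burst_duration_s * rate)))
        if i1 > i0:
            trace[i0:i1] += amp * rng.normal(0.0, 1.0, size=i1 - i0)

    cr_present = bool(rng.uniform() < cfg.cr_prob)
    cr_latency = None
    if cr_present:
        lo, hi = 0.050, protocol.us_onset_s
        while True:  # truncated normal on [50 ms, US onset)
            cr_latency = rng.normal(cfg.cr_latency_mean_s, cfg.cr_latency_sd_s)
            if lo <= cr_latency < hi:
                break
        add_burst(cr_latency, cfg.cr_amp)

    ur_onset = None
    if kind is TrialKind.paired:
        ur_onset = protocol.us_onset_s + cfg.ur_latency_s
        add_burst(ur_onset, cfg.ur_amp)
    return trace, EmgTrialInfo(cr_present, cr_latency, ur_onset)


def _trial_kinds(config: GeneratorConfig, stage_idx: int) -> list[TrialKind]:
    """Fixed pseudo-random CS-alone positions, never at trial 0.

    Positions are drawn without adjacency so every probe trial has its own
    immediately preceding paired trial (US omissions are spaced out, as in
    the probabilistic design the protocol establishes).
    """
    n_total = config.n_paired + config.n_cs_alone
    kinds = [TrialKind.paired] * n_total
    if config.n_cs_alone:
        rng = np.random.default_rng(
            np.random.SeedSequence(config.seed, spawn_key=(_STREAM_LAYOUT, stage_idx))
        )
        while True:
            positions = np.sort(
                rng.choice(np.arange(1, n_total), size=config.n_cs_alone, replace=False)
            )
            if config.n_cs_alone == 1 or np.all(np.diff(positions) > 1):
                break
            if config.n_cs_alone > (n_total - 1 + 1) // 2:  # adjacency unavoidable
                break
        for pos in positions:
            kinds[int(pos)] = TrialKind.cs_alone
    return kinds


def generate_session(
    config: GeneratorConfig,
    stage: SessionStage,
    return_truth: bool = False,
):
    """Generate one full session at the given learning stage.

    Deterministic under ``config.seed``: every (trial, unit) pair draws from
    its own counter-split random stream, so the output is independent of
    generation order. With ``return_truth`` the per-trial
    :class:`EmgTrialInfo` list is returned alongside the session.
    """
    config.validate()
    proto = config.protocol
    profile: StageRateProfile = config.rate_profiles[stage]
    emg_cfg: EmgGenConfig = config.emg_configs[stage]
    profile.validate(proto)
    emg_cfg.validate(proto)
    stage_idx = _STAGE_INDEX[stage]

    unit_ids = [f"u{i:03d}" for i in range(config.n_units)]
    gain_rng = np.random.default_rng(
        np.random.SeedSequence(config.seed, spawn_key=(_STREAM_UNIT_GAIN, stage_idx))
    )
    sigma = config.unit_gain_sigma
    # lognormal with mean 1: exp(N(-sigma^2/2, sigma))
    gains = np.exp(gain_rng.normal(-0.5 * sigma**2, sigma, size=config.n_units))

    kinds = _trial_kinds(config, stage_idx)
    trials = []
    truth = []
    for trial_id, kind in enumerate(kinds):
        emg_rng = np.random.default_rng(
            np.random.SeedSequence(config.seed, spawn_key=(_STREAM_EMG, stage_idx, trial_id))
        )
        emg, info = simulate_emg_trial(emg_cfg, proto, kind, emg_rng)
        spikes = {}
        for u, (unit_id, gain) in enumerate(zip(unit_ids, gains)):
            fn = rate_function(profile, proto, kind, gain=float(gain))
            spike_rng = np.random.default_rng(
                np.random.SeedSequence(
                    config.seed, spawn_key=(_STREAM_SPIKES, stage_idx, trial_id, u)
                )
            )
            spikes[unit_id] = simulate_spike_train(fn, proto, profile.refractory_s, spike_rng)
        trials.append(Trial(trial_id=trial_id, kind=kind, emg=emg, spikes=spikes))
        truth.append(info)

    session = Session(stage=stage, protocol=proto, trials=trials, units=unit_ids)
    if return_truth:
        return session, truth
    return session
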