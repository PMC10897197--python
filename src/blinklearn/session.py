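"""Domain model for delay eyeblink-conditioning recording sessions.

A session holds trial-aligned single-unit spike trains and orbicularis-oculi
EMG traces for one recording stage of the conditioning protocol. Time zero is
the onset of the conditioned stimulus (CS, a tone); the unconditioned stimulus
(US, an air puff) starts 250 ms later and co-terminates with the CS. Each
trial spans a fixed epoch (default -1 s to +2 s around CS onset).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "StimulusProtocol",
    "SessionStage",
    "TrialKind",
    "Trial",
    "UnitRecording",
    "Session",
    "Violation",
    "validate_session",
    "SessionValidationError",
]

#: Tolerance for float comparisons of protocol timing constants.
_TIME_TOL = 1e-9


class SessionStage(str, enum.Enum):
    """Learning stage at which a session was recorded."""

    initial = "initial"
    halfway = "halfway"
    final = "final"


class TrialKind(str, enum.Enum):
    """Paired CS-US trial or a CS-alone probe trial (US omitted)."""

    paired = "paired"
    cs_alone = "cs_alone"


@dataclass(frozen=True)
class StimulusProtocol:
    """Timing constants of the delay conditioning paradigm.

    Defaults follow the standard rabbit delay paradigm: a 350 ms tone CS, a
    100 ms air-puff US starting 250 ms after CS onset (the two co-terminate),
    trials cut from 1 s before to 2 s after tone onset, EMG sampled at 5 kHz.
    """

    cs_onset_s: float = 0.0
    cs_duration_s: float = 0.350
    us_onset_s: float = 0.250
    us_duration_s: float = 0.100
    epoch_start_s: float = -1.0
    epoch_end_s: float = 2.0
    emg_rate_hz: float = 5000.0

    @property
    def cs_offset_s(self) -> float:
        return self.cs_onset_s + self.cs_duration_s

    @property
    def us_offset_s(self) -> float:
        return self.us_onset_s + self.us_duration_s

    @property
    def epoch_duration_s(self) -> float:
        return self.epoch_end_s - self.epoch_start_s

    @property
    def n_emg_samples(self) -> int:
        return int(round(self.epoch_duration_s * self.emg_rate_hz))

    def emg_times(self) -> np.ndarray:
        """Sample times (s, relative to CS onset) of the EMG trace."""
        return self.epoch_start_s + np.arange(self.n_emg_samples) / self.emg_rate_hz

    def to_dict(self) -> dict:
        return {
            "cs_onset_s": self.cs_onset_s,
            "cs_duration_s": self.cs_duration_s,
            "us_onset_s": self.us_onset_s,
            "us_duration_s": self.us_duration_s,
            "epoch_start_s": self.epoch_start_s,
            "epoch_end_s": self.epoch_end_s,
            "emg_rate_hz": self.emg_rate_hz,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "StimulusProtocol":
        return cls(**{k: float(d[k]) for k in cls().to_dict()})


@dataclass
class Trial:
    """One trial: an EMG trace plus the spike train of every unit.

    Spike times are in seconds relative to CS onset, strictly increasing
    within a unit, and confined to the epoch.
    """

    trial_id: int
    kind: TrialKind
    emg: np.ndarray
    spikes: dict[str, np.ndarray] = field(default_factory=dict)


@dataclass
class UnitRecording:
    """Per-unit view over a session: one spike train per selected trial.

    A unit belongs to exactly one session (units are never tracked across
    recording days). ``suppressed`` flags units inhibited rather than
    activated by the stimuli; population analyses exclude them by default.
    """

    unit_id: str
    stage: SessionStage
    trains: list[np.ndarray]
    trial_kinds: list[TrialKind]
    suppressed: bool = False

    @property
    def n_trials(self) -> int:
        return len(self.trains)


@dataclass
class Session:
    """An ordered collection of trials recorded at one learning stage."""

    stage: SessionStage
    protocol: StimulusProtocol
    trials: list[Trial]
    units: list[str]
    suppressed_units: frozenset = frozenset()

    @property
    def paired_trials(self) -> list[Trial]:
        return [t for t in self.trials if t.kind is TrialKind.paired]

    @property
    def cs_alone_trials(self) -> list[Trial]:
        return [t for t in self.trials if t.kind is TrialKind.cs_alone]

    @property
    def active_units(self) -> list[str]:
        return [u for u in self.units if u not in self.suppressed_units]

    def unit_recording(
        self,
        unit_id: str,
        kind: TrialKind | None = TrialKind.paired,
        trials: Iterable[Trial] | None = None,
    ) -> UnitRecording:
        """Spike trains of one unit across trials.

        By default only paired trials are included (the PSTH convention of
        the analysis); pass ``kind=None`` for all trials or an explicit
        ``trials`` subset.
        """
        if trials is None:
            trials = self.trials if kind is None else [
                t for t in self.trials if t.kind is kind
            ]
        trials = list(trials)
        empty = np.empty(0, dtype=float)
        return UnitRecording(
            unit_id=unit_id,
            stage=self.stage,
            trains=[np.asarray(t.spikes.get(unit_id, empty), dtype=float) for t in trials],
            trial_kinds=[t.kind for t in trials],
            suppressed=unit_id in self.suppressed_units,
        )

    def unit_recordings(
        self,
        kind: TrialKind | None = TrialKind.paired,
        include_suppressed: bool = False,
        trials: Iterable[Trial] | None = None,
    ) -> list[UnitRecording]:
        units = self.units if include_suppressed else self.active_units
        return [self.unit_recording(u, kind=kind, trials=trials) for u in units]


@dataclass(frozen=True)
class Violation:
    """A single invariant violation found by :func:`validate_session`."""

    type_name: str
    field_name: str
    message: str
    trial_id: int | None = None
    unit_id: str | None = None

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        loc = []
        if self.trial_id is not None:
            loc.append(f"trial {self.trial_id}")
        if self.unit_id is not None:
            loc.append(f"unit {self.unit_id}")
        where = f" [{', '.join(loc)}]" if loc else ""
        return f"{self.type_name}.{self.field_name}{where}: {self.message}"


class SessionValidationError(ValueError):
    """Raised when a session fails validation on read."""

    def __init__(self, violations: list[Violation]):
        self.violations = violations
        super().__init__(
            "session failed validation:\n" + "\n".join(str(v) for v in violations)
        )


def _validate_protocol(p: StimulusProtocol) -> list[Violation]:
    out = []
    if p.cs_onset_s > p.us_onset_s + _TIME_TOL:
        out.append(Violation("StimulusProtocol", "us_onset_s", "CS onset must precede US onset"))
    if not math.isclose(p.us_offset_s, p.cs_offset_s, abs_tol=_TIME_TOL):
        out.append(
            Violation(
                "StimulusProtocol",
                "us_duration_s",
                "CS and US must co-terminate "
                f"(US offset {p.us_offset_s} != CS offset {p.cs_offset_s})",
            )
        )
    if p.epoch_start_s >= p.cs_onset_s:
        out.append(Violation("StimulusProtocol", "epoch_start_s", "epoch must start before CS onset"))
    if p.epoch_end_s <= p.cs_offset_s:
        out.append(Violation("StimulusProtocol", "epoch_end_s", "epoch must extend past CS offset"))
    if p.emg_rate_hz <= 0:
        out.append(Violation("StimulusProtocol", "emg_rate_hz", "sampling rate must be positive"))
    return out


def validate_session(session: Session) -> list[Violation]:
    """Check every structural invariant; return violations (empty list if valid).

    Violations are data, not exceptions: callers decide whether to raise.
    """
    out: list[Violation] = []
    p = session.protocol
    out.extend(_validate_protocol(p))

    if not isinstance(session.stage, SessionStage):
        out.append(Violation("Session", "stage", f"unknown stage {session.stage!r}"))

    unit_set = set(session.units)
    if len(unit_set) != len(session.units):
        out.append(Violation("Session", "units", "duplicate unit ids"))
    if not session.suppressed_units <= unit_set:
        out.append(Violation("Session", "suppressed_units", "flagged unit not in unit list"))

    seen_paired = False
    for i, trial in enumerate(session.trials):
        if trial.trial_id != i:
            out.append(
                Violation("Trial", "trial_id", f"expected ordinal {i}, got {trial.trial_id}",
                          trial_id=trial.trial_id)
            )
        if not isinstance(trial.kind, TrialKind):
            out.append(Violation("Trial", "kind", f"unknown kind {trial.kind!r}", trial_id=i))
        elif trial.kind is TrialKind.cs_alone and not seen_paired:
            out.append(
                Violation("Session", "trials", "cs_alone trial has no preceding paired trial",
                          trial_id=i)
            )
        if isinstance(trial.kind, TrialKind) and trial.kind is TrialKind.paired:
            seen_paired = True

        n_expected = p.n_emg_samples
        if len(trial.emg) != n_expected:
            out.append(
                Violation("Trial", "emg",
                          f"expected {n_expected} samples, got {len(trial.emg)}", trial_id=i)
            )
        for unit_id, train in trial.spikes.items():
            train = np.asarray(train)
            if unit_id not in unit_set:
                out.append(
                    Violation("Trial", "spikes", "spike train for unknown unit",
                              trial_id=i, unit_id=unit_id)
                )
            if train.size and (
                train[0] < p.epoch_start_s - _TIME_TOL or train[-1] > p.epoch_end_s + _TIME_TOL
            ):
                out.append(
                    Violation("Trial", "spikes", "spike time outside epoch",
                              trial_id=i, unit_id=unit_id)
                )
            if train.size > 1 and not np.all(np.diff(train) > 0):
                out.append(
                    Violation("Trial", "spikes", "spike times not strictly increasing",
                              trial_id=i, unit_id=unit_id)
                )
    return out
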