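"""EMG preprocessing, changepoint onset detection, and CR scoring.

The orbicularis-oculi EMG is detrended, high-pass filtered at 100 Hz
(zero-phase, 4th-order Butterworth) and rectified. Response onsets in the
averaged rectified trace are estimated with a single two-region changepoint:
the split that minimizes the summed squared deviation of each region from
its own mean. Conditioned responses (CRs) are scored per trial as sustained
suprathreshold activity starting at least 50 ms after CS onset and before
US onset.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .session import Session, StimulusProtocol, TrialKind

__all__ = [
    "RectifiedEmg",
    "ChangepointResult",
    "CrResult",
    "preprocess_emg",
    "average_rectified_emg",
    "detect_emg_onset",
    "detect_cr",
    "cr_percentage",
    "session_average_emg",
]

#: Earliest admissible CR onset after CS presentation (s); earlier eyelid
#: activity is treated as a spontaneous blink (alpha response), not a CR.
CR_MIN_LATENCY_S = 0.050


@dataclass
class RectifiedEmg:
    """A rectified (nonnegative) EMG trace aligned to the trial epoch."""

    samples: np.ndarray
    rate_hz: float
    epoch_start_s: float

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)

    def times(self) -> np.ndarray:
        return self.epoch_start_s + np.arange(self.samples.size) / self.rate_hz

    def index_of(self, t_s: float) -> int:
        return int(round((t_s - self.epoch_start_s) * self.rate_hz))

    def time_of(self, index: int) -> float:
        return self.epoch_start_s + index / self.rate_hz


@dataclass(frozen=True)
class ChangepointResult:
    """Single two-region changepoint of a trace (response onset estimate)."""

    onset_time_s: float
    split_index: int  # split lies between samples split_index-1 and split_index
    pre_mean: float
    post_mean: float
    total_sse: float
    search_domain: tuple[float, float]


@dataclass(frozen=True)
class CrResult:
    """Conditioned-response call for one trial."""

    present: bool
    latency_s: float | None
    threshold_used: float
    baseline_mean: float
    baseline_sd: float
    degenerate_baseline: bool = False


def preprocess_emg(
    raw: np.ndarray,
    rate_hz: float,
    cutoff_hz: float = 100.0,
    epoch_start_s: float = -1.0,
    detrend: str = "linear",
) -> RectifiedEmg:
    """Detrend, high-pass filter (zero-phase) and rectify a raw EMG trace.

    Parameters
    ----------
    detrend:
        ``"linear"`` removes a least-squares line (slow drift plus DC),
        ``"constant"`` removes the mean only.
    """
    if rate_hz <= 2 * cutoff_hz:
        raise ValueError(
            f"sampling rate {rate_hz} Hz too low for a {cutoff_hz} Hz high-pass"
        )
    x = signal.detrend(np.asarray(raw, dtype=float), type=detrend)
    sos = signal.butter(4, cutoff_hz, btype="highpass", fs=rate_hz, output="sos")
    x = signal.sosfiltfilt(sos, x)
    return RectifiedEmg(np.abs(x), rate_hz=rate_hz, epoch_start_s=epoch_start_s)


def average_rectified_emg(trials: list[RectifiedEmg]) -> RectifiedEmg:
    """Pointwise mean of equal-length rectified traces."""
    if not trials:
        raise ValueError("cannot average an empty trial list")
    n = trials[0].samples.size
    if any(t.samples.size != n for t in trials):
        raise ValueError("trials have unequal lengths")
    stacked = np.stack([t.samples for t in trials])
    return RectifiedEmg(
        stacked.mean(axis=0), rate_hz=trials[0].rate_hz, epoch_start_s=trials[0].epoch_start_s
    )


def _split_sse(x: np.ndarray) -> tuple[int, float, np.ndarray]:
    """Best split index and objective via prefix sums (O(n)).

    Returns (k, total_sse, sse_per_split) where ``sse_per_split[j]``
    corresponds to split index j+1.
    """
    n = x.size
    cs = np.cumsum(x)
    cs2 = np.cumsum(x * x)
    k = np.arange(1, n)  # left region has k samples
    left = cs2[k - 1] - cs[k - 1] ** 2 / k
    right = (cs2[-1] - cs2[k - 1]) - (cs[-1] - cs[k - 1]) ** 2 / (n - k)
    sse = left + right
    best = int(np.argmin(sse))  # argmin takes the first minimum: smallest k wins ties
    return best + 1, float(sse[best]), sse


def detect_emg_onset(
    avg: RectifiedEmg,
    search_domain: tuple[float, float] | None = None,
) -> ChangepointResult:
    """Exhaustive single-changepoint (two-region least-squares) onset search.

    The split index k minimizes ``SSE(x[:k]) + SSE(x[k:])`` over the search
    domain; ties break toward the smallest k, and the onset is the time of
    the first post-split sample.
    """
    x = avg.samples
    if search_domain is None:
        i0, i1 = 0, x.size
        search_domain = (avg.epoch_start_s, avg.time_of(x.size))
    else:
        i0 = max(0, avg.index_of(search_domain[0]))
        i1 = min(x.size, avg.index_of(search_domain[1]))
    seg = x[i0:i1]
    if seg.size < 4:
        raise ValueError("changepoint search needs at least 4 samples in the domain")
    k_local, total_sse, _ = _split_sse(seg)
    k = i0 + k_local
    return ChangepointResult(
        onset_time_s=avg.time_of(k),
        split_index=k,
        pre_mean=float(seg[:k_local].mean()),
        post_mean=float(seg[k_local:].mean()),
        total_sse=total_sse,
        search_domain=(float(search_domain[0]), float(search_domain[1])),
    )


def _moving_average(x: np.ndarray, w: int) -> np.ndarray:
    """Centered moving average with edges truncated to available samples."""
    if w <= 1:
        return x
    kernel = np.ones(w)
    sums = np.convolve(x, kernel, mode="same")
    counts = np.convolve(np.ones_like(x), kernel, mode="same")
    return sums / counts


def detect_cr(
    trial_emg: RectifiedEmg,
    protocol: StimulusProtocol,
    k_sd: float = 3.0,
    min_dur_s: float = 0.010,
    smooth_s: float = 0.005,
    abs_floor: float = 1e-12,
) -> CrResult:
    """Score one trial for a conditioned response.

    A CR is sustained activity of the rectified trace above
    ``baseline_mean + k_sd * baseline_SD`` for at least ``min_dur_s``,
    beginning in [50 ms, US onset). Baseline statistics come from the
    pre-CS segment. Thresholding is applied to a short moving-average
    envelope (``smooth_s``; 0 disables) because single rectified-noise
    samples cannot stay suprathreshold for tens of milliseconds.
    """
    x = trial_emg.samples
    rate = trial_emg.rate_hz
    w = max(1, int(round(smooth_s * rate)))
    env = _moving_average(x, w)

    i_cs = trial_emg.index_of(protocol.cs_onset_s)
    baseline = env[:i_cs]
    if baseline.size < 2:
        raise ValueError("trace does not cover a pre-CS baseline")
    b_mean, b_sd = float(baseline.mean()), float(baseline.std(ddof=1))
    degenerate = b_sd == 0.0
    threshold = max(b_mean + k_sd * b_sd, abs_floor) if degenerate else b_mean + k_sd * b_sd

    above = env > threshold
    min_run = max(1, int(round(min_dur_s * rate)))
    lo = trial_emg.index_of(CR_MIN_LATENCY_S)
    hi = trial_emg.index_of(protocol.us_onset_s)

    # run starts: first sample of each maximal suprathreshold run
    padded = np.concatenate(([False], above, [False]))
    starts = np.flatnonzero(padded[1:].astype(int) - padded[:-1].astype(int) == 1)
    ends = np.flatnonzero(padded[1:].astype(int) - padded[:-1].astype(int) == -1)
    for s, e in zip(starts, ends):
        if e - s >= min_run and lo <= s < hi:
            return CrResult(True, trial_emg.time_of(int(s)), threshold, b_mean, b_sd, degenerate)
    return CrResult(False, None, threshold, b_mean, b_sd, degenerate)


def cr_percentage(
    session: Session,
    k_sd: float = 3.0,
    min_dur_s: float = 0.010,
    smooth_s: float = 0.005,
) -> float:
    """Percentage of paired trials containing a conditioned response."""
    paired = session.paired_trials
    if not paired:
        raise ValueError("session has no paired trials")
    proto = session.protocol
    n_cr = 0
    for trial in paired:
        rect = preprocess_emg(
            trial.emg, proto.emg_rate_hz, epoch_start_s=proto.epoch_start_s
        )
        if detect_cr(rect, proto, k_sd=k_sd, min_dur_s=min_dur_s, smooth_s=smooth_s).present:
            n_cr += 1
    return 100.0 * n_cr / len(paired)


def session_average_emg(
    session: Session, kind: TrialKind | None = TrialKind.paired
) -> RectifiedEmg:
    """Rectified-and-averaged EMG over the session's trials of one kind."""
    proto = session.protocol
    trials = session.trials if kind is None else [t for t in session.trials if t.kind is kind]
    rects = [
        preprocess_emg(t.emg, proto.emg_rate_hz, epoch_start_s=proto.epoch_start_s)
        for t in trials
    ]
    return average_rectified_emg(rects)
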