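"""Lag-scan cross-correlation between population firing and rectified EMG.

Both series are reduced to a 10 ms bin grid. The spike profile over the
350 ms CS-US period (35 bins) is correlated with 35-bin EMG segments slid
over the full epoch on a lag grid (default -100..+180 ms in 10 ms steps).
Positive lags mean the neural activity precedes the muscle: the EMG segment
is taken later in time than the spike segment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .emg import RectifiedEmg
from .session import StimulusProtocol

__all__ = ["LagScanResult", "default_lags_ms", "emg_to_bins", "lag_scan", "best_lag"]


def default_lags_ms(lo: int = -100, hi: int = 180, step: int = 10) -> np.ndarray:
    """The canonical lag grid: -100..+180 ms in 10 ms steps (29 lags)."""
    return np.arange(lo, hi + step, step)


@dataclass
class LagScanResult:
    """Correlation per lag; undefined (zero-variance) lags are NaN."""

    lags_ms: np.ndarray
    r_values: np.ndarray
    best_lag_ms: float
    best_r: float


def emg_to_bins(
    avg_emg: RectifiedEmg, protocol: StimulusProtocol, bin_s: float = 0.010
) -> np.ndarray:
    """Per-bin mean of the rectified EMG over the full epoch grid."""
    samples_per_bin = bin_s * avg_emg.rate_hz
    n_bins = int(round(protocol.epoch_duration_s / bin_s))
    if abs(samples_per_bin - round(samples_per_bin)) > 1e-9:
        raise ValueError("bin grid must divide the EMG sampling grid")
    spb = int(round(samples_per_bin))
    x = avg_emg.samples
    if x.size != n_bins * spb:
        raise ValueError("EMG trace does not cover the epoch exactly")
    return x.reshape(n_bins, spb).mean(axis=1)


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return np.nan
    return float(np.corrcoef(a, b)[0, 1])


def lag_scan(
    spike_bins: np.ndarray,
    emg_bins: np.ndarray,
    protocol: StimulusProtocol,
    bin_s: float = 0.010,
    lags_ms: np.ndarray | None = None,
) -> LagScanResult:
    """Correlate the CS-US spike profile with lag-shifted EMG segments.

    ``spike_bins`` covers [CS onset, CS offset) — 35 bins at defaults;
    ``emg_bins`` covers the full epoch so a constant-length segment exists
    at every lag, keeping r values comparable across lags.
    """
    spike_bins = np.asarray(spike_bins, dtype=float)
    emg_bins = np.asarray(emg_bins, dtype=float)
    if lags_ms is None:
        lags_ms = default_lags_ms()
    lags_ms = np.asarray(lags_ms)

    n_seg = spike_bins.size
    i_cs = int(round((protocol.cs_onset_s - protocol.epoch_start_s) / bin_s))
    r_values = np.empty(lags_ms.size)
    for i, lag in enumerate(lags_ms):
        shift = int(round(lag / (1000.0 * bin_s)))
        j0 = i_cs + shift
        if j0 < 0 or j0 + n_seg > emg_bins.size:
            raise ValueError(f"EMG bins do not cover lag {lag} ms")
        r_values[i] = _pearson(spike_bins, emg_bins[j0 : j0 + n_seg])

    result = LagScanResult(lags_ms=lags_ms, r_values=r_values, best_lag_ms=np.nan, best_r=np.nan)
    if np.any(np.isfinite(r_values)):
        result.best_lag_ms, result.best_r = best_lag(result)
    return result


def best_lag(result: LagScanResult) -> tuple[float, float]:
    """Lag with the maximum r; ties break to smallest |lag|, then more negative."""
    r = result.r_values
    valid = np.isfinite(r)
    if not np.any(valid):
        raise ValueError("all lags are undefined (zero-variance segments)")
    r_max = np.max(r[valid])
    candidates = [
        (abs(lag), lag)
        for lag, ri, ok in zip(result.lags_ms, r, valid)
        if ok and ri == r_max
    ]
    lag = min(candidates)[1]
    return float(lag), float(r_max)
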