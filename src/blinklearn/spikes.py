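"""PSTHs with per-bin significance tracing, window statistics, and ISIs.

The population PSTH uses 10 ms half-open bins over the trial epoch (300 bins
for the default -1..+2 s epoch). Each bin is tested across units with a
one-sample Wilcoxon signed-rank test and the 300 p-values are corrected with
the Benjamini-Hochberg step-up FDR procedure; a smoothed trace of the
adjusted p-values is kept for display only. Window statistics pool per-unit
10 ms bin counts inside four canonical windows (spontaneous / CS / CS-US /
late) and compare them with the Wilcoxon rank-sum test. Interspike-interval
statistics use 4 ms histogram bins.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .session import StimulusProtocol, UnitRecording

__all__ = [
    "PsthResult",
    "TimeWindows",
    "IsiStats",
    "bin_edges_for",
    "bin_spike_counts",
    "per_bin_signed_rank",
    "bh_fdr",
    "smooth_pvalues",
    "first_significant_bin",
    "compute_psth",
    "window_spike_counts",
    "ranksum_windows",
    "compute_isis",
    "isi_stats",
]


@dataclass(frozen=True)
class TimeWindows:
    """The four canonical analysis windows, half-open [left, right) in s.

    The CS-US window's nominal "251 ms" left edge is read as the 10 ms bin
    starting at 250 ms — the only grid-consistent interpretation.
    """

    spontaneous: tuple[float, float] = (-1.0, 0.0)
    cs: tuple[float, float] = (0.0, 0.250)
    cs_us: tuple[float, float] = (0.250, 0.350)
    late: tuple[float, float] = (0.350, 2.0)

    def items(self):
        return [
            ("spontaneous", self.spontaneous),
            ("cs", self.cs),
            ("cs_us", self.cs_us),
            ("late", self.late),
        ]


@dataclass
class PsthResult:
    """Population PSTH with its per-bin significance trace."""

    bin_edges: np.ndarray
    per_unit_counts: np.ndarray  # units x bins, trial-averaged counts
    mean_counts: np.ndarray
    p_raw: np.ndarray
    p_adjusted: np.ndarray
    sig_mask: np.ndarray
    smoothed_p: np.ndarray
    onset_latency_s: float | None
    q: float = 0.05


@dataclass
class IsiStats:
    """Histogram and location statistics of an ISI sample (all in ms)."""

    isis_ms: np.ndarray
    bin_edges_ms: np.ndarray
    histogram: np.ndarray
    mode_ms: float
    median_ms: float
    mean_ms: float


def bin_edges_for(protocol: StimulusProtocol, bin_s: float = 0.010) -> np.ndarray:
    """Half-open bin grid covering the epoch, left edges labelling bins."""
    if bin_s <= 0:
        raise ValueError("bin_s must be positive")
    n_bins = int(round(protocol.epoch_duration_s / bin_s))
    return protocol.epoch_start_s + bin_s * np.arange(n_bins + 1)


def bin_spike_counts(
    units: list[UnitRecording],
    protocol: StimulusProtocol,
    bin_s: float = 0.010,
) -> tuple[np.ndarray, np.ndarray]:
    """Trial-averaged spike counts per bin for each unit.

    Returns ``(bin_edges, matrix)`` with ``matrix[u, b]`` the mean over unit
    u's trials of the spike count in bin b. A spike exactly at the epoch end
    is counted in the last bin, so row sums times trial counts conserve the
    total in-epoch spike count.
    """
    if not units:
        raise ValueError("need at least one unit")
    edges = bin_edges_for(protocol, bin_s)
    mat = np.zeros((len(units), edges.size - 1))
    for u, rec in enumerate(units):
        if not rec.trains:
            continue
        for train in rec.trains:
            mat[u] += np.histogram(train, bins=edges)[0]
        mat[u] /= len(rec.trains)
    return edges, mat


def per_bin_signed_rank(matrix: np.ndarray) -> np.ndarray:
    """Two-sided one-sample Wilcoxon signed-rank p per column, against zero.

    Zero entries are discarded (standard Wilcoxon reduction); an all-zero
    column yields p = 1 by convention. Requires >= 2 rows (units).
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[0] < 2:
        raise ValueError("signed-rank trace needs a units x bins matrix with >= 2 units")
    p = np.ones(matrix.shape[1])
    for b in range(matrix.shape[1]):
        col = matrix[:, b]
        col = col[col != 0.0]
        if col.size == 0:
            continue
        p[b] = stats.wilcoxon(col, alternative="two-sided", method="auto").pvalue
    return p


def bh_fdr(p_raw: np.ndarray, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up FDR: (adjusted p, rejection mask)."""
    p_raw = np.asarray(p_raw, dtype=float)
    if not 0 < q < 1:
        raise ValueError("q must lie in (0, 1)")
    if np.any((p_raw < 0) | (p_raw > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, p_adj, _, _ = multipletests(p_raw, alpha=q, method="fdr_bh")
    return p_adj, reject


def smooth_pvalues(p_adjusted: np.ndarray, span: float = 0.8) -> np.ndarray:
    """Centered moving average for display; edges truncate to available samples.

    The window is ``round(span * m)`` forced odd. Significance is always
    decided on the unsmoothed adjusted p-values.
    """
    p = np.asarray(p_adjusted, dtype=float)
    if not 0 < span <= 1:
        raise ValueError("span must lie in (0, 1]")
    m = p.size
    w = int(round(span * m))
    if w % 2 == 0:
        w += 1
    if w <= 1 or m == 0:
        return p.copy()
    half = w // 2
    out = np.empty_like(p)
    cs = np.concatenate(([0.0], np.cumsum(p)))
    for i in range(m):
        lo, hi = max(0, i - half), min(m, i + half + 1)
        out[i] = (cs[hi] - cs[lo]) / (hi - lo)
    return out


def first_significant_bin(
    sig_mask: np.ndarray, bin_edges: np.ndarray, from_s: float = 0.0
) -> float | None:
    """Left edge of the first significant bin at or after ``from_s``; None if none."""
    sig_mask = np.asarray(sig_mask, dtype=bool)
    left = np.asarray(bin_edges)[:-1]
    ok = sig_mask & (left >= from_s - 1e-12)
    idx = np.flatnonzero(ok)
    return float(left[idx[0]]) if idx.size else None


def compute_psth(
    units: list[UnitRecording],
    protocol: StimulusProtocol,
    bin_s: float = 0.010,
    q: float = 0.05,
    span: float = 0.8,
    baseline_correct: bool = True,
    baseline_window: tuple[float, float] = (-1.0, 0.0),
) -> PsthResult:
    """Full PSTH significance pipeline for a unit population.

    With ``baseline_correct`` (default) each unit's mean spontaneous-window
    bin count is subtracted before the per-bin signed-rank test, so the
    trace marks bins where the population departs from its own ongoing
    baseline — the reading under which onset latencies are meaningful.
    """
    edges, counts = bin_spike_counts(units, protocol, bin_s)
    if baseline_correct:
        left = edges[:-1]
        sel = (left >= baseline_window[0] - 1e-12) & (left < baseline_window[1] - 1e-12)
        tested = counts - counts[:, sel].mean(axis=1, keepdims=True)
    else:
        tested = counts
    p_raw = per_bin_signed_rank(tested)
    p_adj, mask = bh_fdr(p_raw, q)
    return PsthResult(
        bin_edges=edges,
        per_unit_counts=counts,
        mean_counts=counts.mean(axis=0),
        p_raw=p_raw,
        p_adjusted=p_adj,
        sig_mask=mask,
        smoothed_p=smooth_pvalues(p_adj, span),
        onset_latency_s=first_significant_bin(mask, edges, from_s=0.0),
        q=q,
    )


def window_spike_counts(
    units: list[UnitRecording],
    protocol: StimulusProtocol,
    windows: TimeWindows = TimeWindows(),
    bin_s: float = 0.010,
) -> dict[str, np.ndarray]:
    """Pooled per-unit 10 ms bin counts for each analysis window.

    For each window the result concatenates, over units, the trial-averaged
    counts of every bin whose left edge falls inside the window.
    """
    edges, counts = bin_spike_counts(units, protocol, bin_s)
    left = edges[:-1]
    out = {}
    for name, (lo, hi) in windows.items():
        sel = (left >= lo - 1e-12) & (left < hi - 1e-12)
        out[name] = counts[:, sel].ravel()
    return out


def ranksum_windows(dist_a: np.ndarray, dist_b: np.ndarray) -> float:
    """Two-sided Wilcoxon rank-sum p-value (exact for small untied samples)."""
    dist_a, dist_b = np.asarray(dist_a), np.asarray(dist_b)
    if dist_a.size == 0 or dist_b.size == 0:
        raise ValueError("rank-sum test needs two nonempty samples")
    return float(
        stats.mannwhitneyu(dist_a, dist_b, alternative="two-sided", method="auto").pvalue
    )


def compute_isis(train: np.ndarray, window: tuple[float, float]) -> np.ndarray:
    """ISIs (ms) between consecutive spikes that both lie in the window."""
    train = np.asarray(train, dtype=float)
    if train.size < 2:
        return np.empty(0)
    lo, hi = window
    inside = (train >= lo) & (train < hi)
    both = inside[:-1] & inside[1:]
    return 1000.0 * np.diff(train)[both]


def isi_stats(isis_ms: np.ndarray, bin_ms: float = 4.0) -> IsiStats:
    """Histogram (4 ms bins), mode (center of tallest bin), median and mean."""
    isis_ms = np.asarray(isis_ms, dtype=float)
    if isis_ms.size == 0:
        raise ValueError("cannot summarize an empty ISI sample")
    n_bins = max(1, int(np.ceil((isis_ms.max() + 1e-12) / bin_ms)))
    edges = bin_ms * np.arange(n_bins + 1)
    hist, _ = np.histogram(isis_ms, bins=edges)
    mode_bin = int(np.argmax(hist))  # first maximum: ties break to the smallest bin
    return IsiStats(
        isis_ms=isis_ms,
        bin_edges_ms=edges,
        histogram=hist,
        mode_ms=float(edges[mode_bin] + bin_ms / 2),
        median_ms=float(np.median(isis_ms)),
        mean_ms=float(np.mean(isis_ms)),
    )
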