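"""Between-stage bin-by-bin contrasts and the CS-alone vs last-paired contrast.

Stage comparisons test each 10 ms bin with a pooled-variance two-sample
t-test across units at an uncorrected threshold (the between-stage figure
convention); the US-omission analysis contrasts the CS-alone trials with,
for each one, the nearest preceding paired trial, so both subsets contain
the same number of trials drawn from the same part of the session.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .session import Session, Trial, TrialKind
from .spikes import bh_fdr, bin_spike_counts

__all__ = [
    "BinContrast",
    "CsAloneContrast",
    "binwise_two_sample",
    "select_last_paired_before_alone",
    "cs_alone_contrast",
    "neural_lead_time",
]


@dataclass
class BinContrast:
    """Per-bin contrast between two unit-count matrices."""

    bin_edges: np.ndarray
    mean_a: np.ndarray
    mean_b: np.ndarray
    p_per_bin: np.ndarray
    sig_mask: np.ndarray
    alpha: float
    test_used: str


@dataclass
class CsAloneContrast:
    """Last-paired vs CS-alone PSTH contrast (US-omission analysis)."""

    bin_edges: np.ndarray
    psth_last_paired: np.ndarray
    psth_cs_alone: np.ndarray
    difference: np.ndarray  # last_paired - cs_alone, per bin
    p_per_bin: np.ndarray
    sig_mask: np.ndarray
    alpha: float
    n_alone: int
    n_last_paired: int
    test_used: str


def _binwise_t(matrix_a: np.ndarray, matrix_b: np.ndarray) -> np.ndarray:
    with np.errstate(invalid="ignore", divide="ignore"):
        res = stats.ttest_ind(matrix_a, matrix_b, axis=0, equal_var=True)
        p = np.asarray(res.pvalue, dtype=float)
    # zero pooled variance: identical constants -> no evidence (p=1),
    # different constants -> infinitely strong evidence (p=0)
    bad = ~np.isfinite(p)
    if np.any(bad):
        same = np.isclose(matrix_a.mean(axis=0), matrix_b.mean(axis=0))
        p[bad] = np.where(same[bad], 1.0, 0.0)
    return p


def binwise_two_sample(
    matrix_a: np.ndarray,
    matrix_b: np.ndarray,
    bin_edges: np.ndarray,
    alpha: float = 0.01,
    correct_fdr: bool = False,
) -> BinContrast:
    """Pooled-variance two-sample t-test per bin across units.

    No multiplicity correction by default (matching the between-stage figure
    convention); ``correct_fdr`` applies BH at ``alpha`` instead.
    """
    matrix_a, matrix_b = np.atleast_2d(matrix_a), np.atleast_2d(matrix_b)
    if matrix_a.shape[0] < 2 or matrix_b.shape[0] < 2:
        raise ValueError("each group needs at least 2 units")
    if matrix_a.shape[1] != matrix_b.shape[1]:
        raise ValueError("bin grids differ between groups")
    p = _binwise_t(matrix_a, matrix_b)
    if correct_fdr:
        _, mask = bh_fdr(p, alpha)
    else:
        mask = p < alpha
    return BinContrast(
        bin_edges=np.asarray(bin_edges),
        mean_a=matrix_a.mean(axis=0),
        mean_b=matrix_b.mean(axis=0),
        p_per_bin=p,
        sig_mask=mask,
        alpha=alpha,
        test_used="two_sample_t",
    )


def select_last_paired_before_alone(session: Session) -> list[Trial]:
    """The nearest preceding paired trial of each CS-alone trial.

    Consecutive CS-alone trials share one preceding paired trial; it is used
    once (duplicates collapsed, with a warning) so the pairing stays
    one-to-one on distinct trials.
    """
    selected: list[Trial] = []
    last_paired: Trial | None = None
    n_alone = 0
    for trial in session.trials:
        if trial.kind is TrialKind.paired:
            last_paired = trial
        else:
            n_alone += 1
            if last_paired is None:
                raise ValueError(
                    f"cs_alone trial {trial.trial_id} has no preceding paired trial"
                )
            if not selected or selected[-1].trial_id != last_paired.trial_id:
                selected.append(last_paired)
    if n_alone and len(selected) < n_alone:
        warnings.warn(
            f"{n_alone} CS-alone trials map to {len(selected)} distinct paired trials; "
            "duplicates collapsed",
            stacklevel=2,
        )
    return selected


def cs_alone_contrast(
    session: Session,
    alpha: float = 0.05,
    test: str = "two_sample_t",
    bin_s: float = 0.010,
) -> CsAloneContrast:
    """Contrast CS-alone trials against their preceding paired trials.

    PSTHs (per-unit, trial-averaged 10 ms bin counts) are computed over each
    trial subset and compared bin by bin across units at ``alpha``
    (uncorrected). ``test`` is ``"two_sample_t"`` (default) or
    ``"signed_rank"`` (paired across units).
    """
    alone = session.cs_alone_trials
    if len(alone) < 2:
        raise ValueError("need at least 2 CS-alone trials")
    last_paired = select_last_paired_before_alone(session)

    units_alone = session.unit_recordings(trials=alone)
    units_paired = session.unit_recordings(trials=last_paired)
    edges, mat_alone = bin_spike_counts(units_alone, session.protocol, bin_s)
    _, mat_paired = bin_spike_counts(units_paired, session.protocol, bin_s)

    if test == "two_sample_t":
        p = _binwise_t(mat_paired, mat_alone)
    elif test == "signed_rank":
        diffs = mat_paired - mat_alone
        p = np.ones(diffs.shape[1])
        for b in range(diffs.shape[1]):
            col = diffs[:, b]
            col = col[col != 0.0]
            if col.size:
                p[b] = stats.wilcoxon(col, alternative="two-sided", method="auto").pvalue
    else:
        raise ValueError(f"unknown test {test!r}")

    psth_paired = mat_paired.mean(axis=0)
    psth_alone = mat_alone.mean(axis=0)
    return CsAloneContrast(
        bin_edges=edges,
        psth_last_paired=psth_paired,
        psth_cs_alone=psth_alone,
        difference=psth_paired - psth_alone,
        p_per_bin=p,
        sig_mask=p < alpha,
        alpha=alpha,
        n_alone=len(alone),
        n_last_paired=len(last_paired),
        test_used=test,
    )


def neural_lead_time(emg_onset_s: float, neural_onset_s: float) -> float:
    """Lead of the neural onset over the EMG onset (positive: spikes first)."""
    if emg_onset_s is None or neural_onset_s is None:
        raise ValueError("both onsets must be defined")
    return emg_onset_s - neural_onset_s
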