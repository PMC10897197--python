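"""End-to-end run: simulate (or load) sessions, analyze, compare, report.

One :class:`RunConfig` drives the whole pipeline; the resulting
:class:`RunReport` is a plain JSON-serializable summary whose regeneration
under the same config is bit-for-bit identical.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .compare import binwise_two_sample, cs_alone_contrast, neural_lead_time
from .coupling import emg_to_bins, lag_scan
from .emg import cr_percentage, detect_emg_onset, session_average_emg
from .io import read_session
from .session import Session, SessionStage, StimulusProtocol
from .simulate import (
    EmgGenConfig,
    GeneratorConfig,
    StageRateProfile,
    generate_session,
)
from .spikes import TimeWindows, compute_isis, compute_psth, isi_stats, window_spike_counts

__all__ = [
    "AnalysisConfig",
    "RunConfig",
    "run_pipeline",
    "analyze_session",
    "load_config",
    "save_config",
]

_STAGES = [SessionStage.initial, SessionStage.halfway, SessionStage.final]


@dataclass(frozen=True)
class AnalysisConfig:
    """All analysis parameters that affect any number in the report."""

    psth_bin_s: float = 0.010
    fdr_q: float = 0.05
    smooth_span: float = 0.8
    windows: TimeWindows = TimeWindows()
    isi_bin_ms: float = 4.0
    cr_k_sd: float = 3.0
    cr_min_dur_s: float = 0.010
    cr_smooth_s: float = 0.005
    lag_lo_ms: int = -100
    lag_hi_ms: int = 180
    lag_step_ms: int = 10
    contrast_alpha: float = 0.01
    cs_alone_alpha: float = 0.05
    cs_alone_test: str = "two_sample_t"
    #: right edge of the EMG changepoint search, seconds past US offset; a
    #: single two-region split on the full epoch locks onto the largest
    #: step, so the search stops shortly after the reflex response.
    emg_domain_pad_s: float = 0.10

    def lags_ms(self) -> np.ndarray:
        return np.arange(self.lag_lo_ms, self.lag_hi_ms + self.lag_step_ms, self.lag_step_ms)

    def emg_search_domain(self, protocol: StimulusProtocol) -> tuple[float, float]:
        return (protocol.epoch_start_s, protocol.us_offset_s + self.emg_domain_pad_s)


@dataclass(frozen=True)
class RunConfig:
    """A full reproducible run: generator, analysis parameters, seed, output."""

    generator: GeneratorConfig = GeneratorConfig()
    analysis: AnalysisConfig = AnalysisConfig()
    seed: int = 0
    output_dir: str | None = None
    #: optional stage -> manifest path; when set, sessions are read instead
    #: of generated and the analysis path is identical.
    session_manifests: dict | None = None
    make_figures: bool = False


def analyze_session(session: Session, analysis: AnalysisConfig = AnalysisConfig()) -> dict:
    """All per-session quantities of the standard analysis, as a plain dict."""
    proto = session.protocol
    units = session.unit_recordings()  # active units, paired trials

    psth = compute_psth(
        units, proto, bin_s=analysis.psth_bin_s, q=analysis.fdr_q, span=analysis.smooth_span
    )
    avg_emg = session_average_emg(session)
    emg_onset = detect_emg_onset(avg_emg, analysis.emg_search_domain(proto))

    win_counts = window_spike_counts(units, proto, analysis.windows, analysis.psth_bin_s)
    window_means = {name: float(np.mean(v)) if v.size else np.nan for name, v in win_counts.items()}

    isi = {}
    for name, window in analysis.windows.items():
        pooled = np.concatenate(
            [compute_isis(train, window) for rec in units for train in rec.trains]
            or [np.empty(0)]
        )
        if pooled.size:
            s = isi_stats(pooled, analysis.isi_bin_ms)
            isi[name] = {
                "mode_ms": s.mode_ms,
                "median_ms": round(s.median_ms, 6),
                "mean_ms": round(s.mean_ms, 6),
                "n": int(pooled.size),
            }
        else:
            isi[name] = {"mode_ms": None, "median_ms": None, "mean_ms": None, "n": 0}

    i_cs = int(round((proto.cs_onset_s - proto.epoch_start_s) / analysis.psth_bin_s))
    n_seg = int(round(proto.cs_duration_s / analysis.psth_bin_s))
    spike_bins = psth.mean_counts[i_cs : i_cs + n_seg]
    emg_bins = emg_to_bins(avg_emg, proto, analysis.psth_bin_s)
    lags = lag_scan(spike_bins, emg_bins, proto, analysis.psth_bin_s, analysis.lags_ms())

    alone = cs_alone_contrast(
        session,
        alpha=analysis.cs_alone_alpha,
        test=analysis.cs_alone_test,
        bin_s=analysis.psth_bin_s,
    )
    left = alone.bin_edges[:-1]
    us_sel = (left >= proto.us_onset_s - 1e-12) & (left < proto.us_offset_s - 1e-12)

    neural_onset = psth.onset_latency_s
    lead_ms = (
        round(1000.0 * neural_lead_time(emg_onset.onset_time_s, neural_onset), 6)
        if neural_onset is not None
        else None
    )
    return {
        "n_units": len(units),
        "n_paired": len(session.paired_trials),
        "n_cs_alone": len(session.cs_alone_trials),
        "cr_pct": round(
            cr_percentage(
                session,
                k_sd=analysis.cr_k_sd,
                min_dur_s=analysis.cr_min_dur_s,
                smooth_s=analysis.cr_smooth_s,
            ),
            6,
        ),
        "emg_onset_ms": round(1000.0 * emg_onset.onset_time_s, 6),
        "neural_onset_ms": None if neural_onset is None else round(1000.0 * neural_onset, 6),
        "neural_emg_lead_ms": lead_ms,
        "window_means": {k: round(v, 6) for k, v in window_means.items()},
        "isi": isi,
        "best_lag_ms": float(lags.best_lag_ms),
        "best_r": round(float(lags.best_r), 6),
        "n_sig_bins": int(np.sum(psth.sig_mask)),
        "cs_alone": {
            "n_alone": alone.n_alone,
            "n_last_paired": alone.n_last_paired,
            "n_sig_bins": int(np.sum(alone.sig_mask)),
            "n_sig_bins_us_window": int(np.sum(alone.sig_mask & us_sel)),
        },
    }


def _stage_contrasts(sessions: dict, analysis: AnalysisConfig) -> dict:
    from .spikes import bin_spike_counts

    mats = {}
    for stage, session in sessions.items():
        edges, mat = bin_spike_counts(
            session.unit_recordings(), session.protocol, analysis.psth_bin_s
        )
        mats[stage] = (edges, mat)
    out = {}
    pairs = [
        (SessionStage.initial, SessionStage.halfway),
        (SessionStage.halfway, SessionStage.final),
        (SessionStage.initial, SessionStage.final),
    ]
    for a, b in pairs:
        if a not in mats or b not in mats:
            continue
        edges, mat_a = mats[a]
        contrast = binwise_two_sample(mat_a, mats[b][1], edges, alpha=analysis.contrast_alpha)
        out[f"{a.value}_vs_{b.value}"] = {
            "alpha": analysis.contrast_alpha,
            "n_sig_bins": int(np.sum(contrast.sig_mask)),
        }
    return out


def _make_figures(sessions: dict, reports: dict, analysis: AnalysisConfig, out_dir: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(2, len(sessions), figsize=(4 * len(sessions), 6), squeeze=False)
    for i, (stage, session) in enumerate(sessions.items()):
        units = session.unit_recordings()
        psth = compute_psth(units, session.protocol, bin_s=analysis.psth_bin_s, q=analysis.fdr_q)
        centers = 0.5 * (psth.bin_edges[:-1] + psth.bin_edges[1:])
        axes[0][i].bar(centers, psth.mean_counts, width=analysis.psth_bin_s)
        axes[0][i].set_title(f"{stage.value}: PSTH")
        axes[0][i].set_xlabel("time from CS onset (s)")
        axes[1][i].plot(centers, psth.smoothed_p)
        axes[1][i].axhline(0.05, ls="--", c="k", lw=0.5)
        axes[1][i].set_title("adjusted p (smoothed)")
    fig.tight_layout()
    fig.savefig(out_dir / "psth.png", dpi=100)
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(6, 4))
    for stage, session in sessions.items():
        avg = session_average_emg(session)
        ax.plot(avg.times(), avg.samples, label=stage.value, lw=0.5)
    ax.set_xlabel("time from CS onset (s)")
    ax.set_ylabel("rectified EMG (a.u.)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(out_dir / "emg.png", dpi=100)
    plt.close(fig)


def run_pipeline(config: RunConfig) -> dict:
    """Execute simulate/load -> analyze -> compare; return the report dict.

    When ``config.output_dir`` is set the report is written there as
    ``report.json`` (plus figures if requested).
    """
    gen = replace(config.generator, seed=config.seed)
    sessions: dict[SessionStage, Session] = {}
    if config.session_manifests:
        for stage_name, path in config.session_manifests.items():
            stage = SessionStage(stage_name)
            sessions[stage] = read_session(path)
    else:
        for stage in _STAGES:
            sessions[stage] = generate_session(gen, stage)

    report = {
        "software": {"name": "blinklearn", "version": __version__},
        "seed": config.seed,
        "config": _config_to_dict(replace(config, generator=gen)),
        "stages": {},
    }
    for stage, session in sessions.items():
        report["stages"][stage.value] = analyze_session(session, config.analysis)
    report["contrasts"] = _stage_contrasts(sessions, config.analysis)

    if config.output_dir is not None:
        out_dir = Path(config.output_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "report.json").write_text(
            json.dumps(report, indent=2, sort_keys=True) + "\n"
        )
        if config.make_figures:
            _make_figures(sessions, report["stages"], config.analysis, out_dir)
    return report


# -- configuration (de)serialization -----------------------------------------


def _config_to_dict(config: RunConfig) -> dict:
    gen, ana = config.generator, config.analysis
    return {
        "seed": config.seed,
        "output_dir": config.output_dir,
        "session_manifests": config.session_manifests,
        "make_figures": config.make_figures,
        "generator": {
            "protocol": gen.protocol.to_dict(),
            "n_units": gen.n_units,
            "n_paired": gen.n_paired,
            "n_cs_alone": gen.n_cs_alone,
            "unit_gain_sigma": gen.unit_gain_sigma,
            "seed": gen.seed,
            "rate_profiles": {
                s.value: dataclasses.asdict(p) for s, p in gen.rate_profiles.items()
            },
            "emg_configs": {
                s.value: dataclasses.asdict(e) for s, e in gen.emg_configs.items()
            },
        },
        "analysis": {
            **{
                f.name: getattr(ana, f.name)
                for f in dataclasses.fields(ana)
                if f.name != "windows"
            },
            "windows": {k: list(v) for k, v in ana.windows.items()},
        },
    }


def _config_from_dict(d: dict) -> RunConfig:
    gd = d.get("generator", {})
    protocol = (
        StimulusProtocol.from_dict(gd["protocol"]) if "protocol" in gd else StimulusProtocol()
    )
    gen_kwargs = {
        k: gd[k]
        for k in ("n_units", "n_paired", "n_cs_alone", "unit_gain_sigma", "seed")
        if k in gd
    }
    if "rate_profiles" in gd:
        gen_kwargs["rate_profiles"] = {
            SessionStage(s): StageRateProfile(**p) for s, p in gd["rate_profiles"].items()
        }
    if "emg_configs" in gd:
        gen_kwargs["emg_configs"] = {
            SessionStage(s): EmgGenConfig(**e) for s, e in gd["emg_configs"].items()
        }
    generator = GeneratorConfig(protocol=protocol, **gen_kwargs)

    ad = dict(d.get("analysis", {}))
    windows = ad.pop("windows", None)
    if windows is not None:
        ad["windows"] = TimeWindows(**{k: tuple(v) for k, v in windows.items()})
    analysis = AnalysisConfig(**ad)
    return RunConfig(
        generator=generator,
        analysis=analysis,
        seed=d.get("seed", 0),
        output_dir=d.get("output_dir"),
        session_manifests=d.get("session_manifests"),
        make_figures=d.get("make_figures", False),
    )


def load_config(path: str | Path) -> RunConfig:
    """Read a RunConfig from YAML (the single entry point for parameters)."""
    with open(path) as fh:
        return _config_from_dict(yaml.safe_load(fh) or {})


def save_config(config: RunConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(_config_to_dict(config), fh, sort_keys=True)
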