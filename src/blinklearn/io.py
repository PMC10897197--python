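"""Reading and writing sessions on disk.

Dialect
-------
* ``manifest.json`` — stage, protocol constants, ordered trial table
  (``trial_id``, ``kind``), unit list with suppressed flags, and the names of
  the spike and EMG files.
* ``spikes.csv`` — header ``unit_id,trial_id,spike_time_s``; UTF-8, LF line
  endings; times written as fixed 6-decimal strings (microsecond precision)
  so a write → read → write cycle is byte-identical.
* EMG — either ``emg.csv`` (``trial_id,sample_index,value``) or a raw
  little-endian float64 matrix ``emg.f64`` laid out trials x samples; both
  readers are provided, the writer picks one via ``emg_format``.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .session import (
    Session,
    SessionStage,
    SessionValidationError,
    StimulusProtocol,
    Trial,
    TrialKind,
    validate_session,
)

__all__ = ["read_session", "write_session"]

_SPIKE_HEADER = "unit_id,trial_id,spike_time_s"


def write_session(session: Session, out_dir: str | Path, emg_format: str = "csv") -> Path:
    """Write ``session`` under ``out_dir`` and return the manifest path.

    Spike times are rounded to microseconds on write; sessions produced by
    the synthetic generator already carry microsecond-rounded times, for
    which the round trip is bit-exact.
    """
    if emg_format not in ("csv", "f64"):
        raise ValueError(f"emg_format must be 'csv' or 'f64', got {emg_format!r}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    spike_lines = [_SPIKE_HEADER]
    for trial in session.trials:
        for unit_id in session.units:
            for t in trial.spikes.get(unit_id, ()):  # deterministic order
                spike_lines.append(f"{unit_id},{trial.trial_id},{t:.6f}")
    (out_dir / "spikes.csv").write_text("\n".join(spike_lines) + "\n", newline="\n")

    n_samples = session.protocol.n_emg_samples
    emg_name = "emg.csv" if emg_format == "csv" else "emg.f64"
    if session.trials:
        emg = np.stack([np.asarray(t.emg, dtype=np.float64) for t in session.trials])
    else:
        emg = np.empty((0, n_samples), dtype=np.float64)
    if emg_format == "csv":
        with open(out_dir / emg_name, "w", newline="\n") as fh:
            fh.write("trial_id,sample_index,value\n")
            for trial, row in zip(session.trials, emg):
                tid = trial.trial_id
                fh.writelines(
                    f"{tid},{j},{v!r}\n" for j, v in enumerate(row.tolist())
                )
    else:
        emg.astype("<f8").tofile(out_dir / emg_name)

    manifest = {
        "stage": session.stage.value,
        "protocol": session.protocol.to_dict(),
        "trials": [{"trial_id": t.trial_id, "kind": t.kind.value} for t in session.trials],
        "units": [
            {"unit_id": u, "suppressed": u in session.suppressed_units}
            for u in session.units
        ],
        "files": {"spikes": "spikes.csv", "emg": emg_name, "emg_format": emg_format},
    }
    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest_path


def read_session(manifest_path: str | Path) -> Session:
    """Read and validate a session; raise :class:`SessionValidationError` if invalid."""
    manifest_path = Path(manifest_path)
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    base = manifest_path.parent

    protocol = StimulusProtocol.from_dict(manifest["protocol"])
    stage = SessionStage(manifest["stage"])
    units = [u["unit_id"] for u in manifest["units"]]
    suppressed = frozenset(u["unit_id"] for u in manifest["units"] if u.get("suppressed"))

    spike_path = base / manifest["files"]["spikes"]
    emg_path = base / manifest["files"]["emg"]
    if not spike_path.exists():
        raise FileNotFoundError(spike_path)
    if not emg_path.exists():
        raise FileNotFoundError(emg_path)

    trial_rows = manifest["trials"]
    n_trials = len(trial_rows)
    n_samples = protocol.n_emg_samples

    emg_format = manifest["files"].get("emg_format", "csv")
    if emg_format == "f64":
        flat = np.fromfile(emg_path, dtype="<f8")
        emg = flat.reshape(n_trials, -1) if n_trials else np.empty((0, n_samples))
    else:
        df = pd.read_csv(emg_path)
        emg = np.zeros((n_trials, n_samples))
        tid_to_row = {row["trial_id"]: i for i, row in enumerate(trial_rows)}
        for tid, grp in df.groupby("trial_id"):
            emg[tid_to_row[int(tid)], grp["sample_index"].to_numpy()] = grp["value"].to_numpy()

    spikes_df = pd.read_csv(spike_path, dtype={"unit_id": str})
    by_trial: dict[int, dict[str, list[float]]] = {}
    for unit_id, tid, t in zip(
        spikes_df["unit_id"], spikes_df["trial_id"], spikes_df["spike_time_s"]
    ):
        by_trial.setdefault(int(tid), {}).setdefault(unit_id, []).append(float(t))

    trials = []
    for i, row in enumerate(trial_rows):
        tid = int(row["trial_id"])
        spikes = {
            u: np.asarray(ts, dtype=float) for u, ts in by_trial.get(tid, {}).items()
        }
        trials.append(Trial(trial_id=tid, kind=TrialKind(row["kind"]), emg=emg[i], spikes=spikes))

    session = Session(
        stage=stage, protocol=protocol, trials=trials, units=units,
        suppressed_units=suppressed,
    )
    violations = validate_session(session)
    if violations:
        raise SessionValidationError(violations)
    return session
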