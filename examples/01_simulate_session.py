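"""Generate a synthetic conditioning session and write it to disk.

A session is one recording day of delay eyeblink conditioning: 60 paired
CS-US trials plus 6 CS-alone probes, each trial spanning -1 s to +2 s around
tone onset, with single-unit spike trains and a 5 kHz orbicularis-oculi EMG
trace.
"""

from blinklearn import SessionStage, default_config, generate_session, write_session

config = default_config(n_units=10, seed=42)
session = generate_session(config, SessionStage.final)

print(f"stage: {session.stage.value}")
print(f"trials: {len(session.trials)} "
      f"({len(session.paired_trials)} paired, {len(session.cs_alone_trials)} CS-alone)")
print(f"units: {len(session.units)}")
n_spikes = sum(len(t) for trial in session.trials for t in trial.spikes.values())
print(f"total spikes: {n_spikes}")

manifest = write_session(session, "scratch/example_session", emg_format="f64")
print(f"written to {manifest}")
# The manifest lists the trial table and points at spikes.csv (one row per
# spike) and the raw float64 EMG matrix; read_session() restores the session.
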