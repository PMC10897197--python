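"""One reproducible end-to-end run driven by a single configuration.

run_pipeline simulates (or loads) one session per learning stage, runs the
whole analysis chain, and returns a JSON-serializable report; the same
config and seed reproduce the report bit for bit. The ``blinklearn run``
shell command wraps exactly this call.
"""

import json

from blinklearn import AnalysisConfig, RunConfig, default_config, run_pipeline

config = RunConfig(
    generator=default_config(n_units=15),
    analysis=AnalysisConfig(fdr_q=0.01),
    seed=123,
)
report = run_pipeline(config)

for stage, rep in report["stages"].items():
    print(
        f"{stage:8s} CR {rep['cr_pct']:5.1f}%  EMG onset {rep['emg_onset_ms']:6.1f} ms  "
        f"neural onset {rep['neural_onset_ms']} ms  best lag {rep['best_lag_ms']:+.0f} ms"
    )
print("\ncontrast summary:", json.dumps(report["contrasts"], sort_keys=True))
print("report is deterministic:", run_pipeline(config) == report)
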