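"""Lag-scan correlation between population firing and the eyelid EMG.

The population spike profile over the 350 ms CS-US period is correlated
with the averaged rectified EMG as the EMG is displaced over lags from
-100 to +180 ms in 10 ms steps. A positive best lag means the neural
activity precedes the muscle.
"""

from blinklearn import (
    SessionStage,
    compute_psth,
    default_config,
    emg_to_bins,
    generate_session,
    lag_scan,
    session_average_emg,
)

for stage in SessionStage:
    session = generate_session(default_config(n_units=40, seed=2), stage)
    proto = session.protocol
    psth = compute_psth(session.unit_recordings(), proto)
    i_cs = int(round((proto.cs_onset_s - proto.epoch_start_s) / 0.010))
    spike_bins = psth.mean_counts[i_cs : i_cs + 35]
    emg_bins = emg_to_bins(session_average_emg(session), proto)
    res = lag_scan(spike_bins, emg_bins, proto)
    n_strong = int((res.r_values > 0.6).sum())
    print(
        f"{stage.value:8s} best lag {res.best_lag_ms:+5.0f} ms  r = {res.best_r:.3f}  "
        f"lags with r > 0.6: {n_strong}"
    )
# The number of strongly correlated lags grows with conditioning as firing
# and eyelid closure become synchronized.
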