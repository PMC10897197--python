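"""EMG onset detection and conditioned-response scoring.

The averaged rectified EMG of a session is segmented with a single
two-region least-squares changepoint: the split minimizing the summed
squared deviation of each side from its own mean marks the response onset.
Individual trials are scored for a conditioned response (CR): sustained
suprathreshold activity starting at least 50 ms after the tone but before
the air puff.
"""

from blinklearn import (
    AnalysisConfig,
    SessionStage,
    cr_percentage,
    default_config,
    detect_emg_onset,
    generate_session,
    session_average_emg,
)

analysis = AnalysisConfig()
for stage in SessionStage:
    session = generate_session(default_config(n_units=2, seed=7), stage)
    avg = session_average_emg(session)
    onset = detect_emg_onset(avg, analysis.emg_search_domain(session.protocol))
    pct = cr_percentage(session)
    print(
        f"{stage.value:8s} EMG onset {1000 * onset.onset_time_s:6.1f} ms   "
        f"CR {pct:5.1f}%   (pre/post means {onset.pre_mean:.2f}/{onset.post_mean:.2f})"
    )
# CR incidence rises steeply across learning while the averaged-EMG onset
# moves from the reflex response (after the 250 ms air puff) toward the
# anticipatory conditioned response.
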