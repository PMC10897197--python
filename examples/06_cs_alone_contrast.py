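"""US-omission analysis: CS-alone trials vs the preceding paired trials.

For each CS-alone probe the nearest preceding paired trial is selected, so
both subsets have the same size and come from the same part of the session.
PSTHs over the two subsets are contrasted bin by bin; significance in the
250-350 ms window (where the puff occurs or is omitted) reveals whether the
firing there is driven by the US itself or by the learned prediction.
"""

import numpy as np

from blinklearn import SessionStage, cs_alone_contrast, default_config, generate_session

for stage in SessionStage:
    session = generate_session(default_config(n_units=40, seed=1), stage)
    res = cs_alone_contrast(session, alpha=0.05)
    left = res.bin_edges[:-1]
    us = (left >= 0.25 - 1e-9) & (left < 0.35 - 1e-9)
    print(
        f"{stage.value:8s} significant bins: total {int(res.sig_mask.sum()):3d}, "
        f"in US window {int(res.sig_mask[us].sum()):2d}   "
        f"max |difference| {np.abs(res.difference).max():.3f} counts/bin"
    )
# Before learning, omitting the puff removes a large US-driven response
# (significant US-window bins); once conditioned the firing is predictive
# and identical whether or not the puff arrives.
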