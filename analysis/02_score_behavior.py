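#!/usr/bin/env python
"""Score conditioned responses from the session's eyelid EMG.

Applies the Hilbert-envelope threshold rules trial by trial and reports CR%
and pre-CR% per block, alongside the generator's ground truth.
"""

import pandas as pd

from _common import RESULTS, SESSION_DIR, announce, load_or_generate
from lecpipe.behavior import score_session

spikes, trials, emg, schedule = load_or_generate(with_emg=True)
announce("computing EMG envelope and CR labels")
scores = score_session(emg, trials, schedule)
scores.trial_df.to_csv(RESULTS / "cr_scores.csv", index=False)
scores.block_df.to_csv(RESULTS / "cr_block_stats.csv", index=False)

truth = pd.read_csv(SESSION_DIR / "ground_truth_cr.csv")["cr_true"].to_numpy()
detected = scores.labels == "CR"
sens = (detected & truth).sum() / max(1, truth.sum())
announce(f"threshold {scores.threshold:.3f} a.u.; detector sensitivity vs "
         f"ground truth {sens:.3f}")
print(scores.block_df.to_string(index=False))
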