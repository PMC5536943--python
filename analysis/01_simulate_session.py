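#!/usr/bin/env python
"""Generate the default synthetic session and report its composition.

Writes the session (spikes, trials, EMG, schedule, ground truth) under
scratch/session/ and a small composition summary to results/.
"""

import numpy as np
import pandas as pd

from _common import RESULTS, SESSION_DIR, announce, load_or_generate

announce("simulating default session (210 trials, 250 cells, 10 kHz EMG)")
spikes, trials, emg, schedule = load_or_generate(with_emg=True)

truth = pd.read_csv(SESSION_DIR / "ground_truth_cells.csv")
summary = truth.groupby("category_label").size().rename("n_cells").reset_index()
summary["fraction"] = summary["n_cells"] / len(truth)
summary.to_csv(RESULTS / "session_composition.csv", index=False)

rates = [len(u.spike_times_s) / trials.end_s for u in spikes]
announce(f"{len(spikes)} cells, median firing rate "
         f"{np.median(rates):.2f} Hz, session length {trials.end_s / 60:.1f} min")
announce(f"responsive fraction (ground truth): {truth['responsive'].mean():.3f}")
print(summary.to_string(index=False))
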