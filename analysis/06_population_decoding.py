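#!/usr/bin/env python
"""Pseudo-population SVM decoding of block identity and binary task-variable
collapses, for trial and ITI epochs.

Each configuration runs 10 subsample runs (the protocol's full 20 doubles
runtime without changing the picture) of 20 train/test resamples = 1200
predictions per run.
"""

from dataclasses import replace

import pandas as pd

from _common import RESULTS, announce, default_config, load_or_generate
from lecpipe.decoding import DecodingSpec, decode

spikes, trials, emg, schedule = load_or_generate()
cfg = default_config()
base = DecodingSpec(n_runs=10)

res_frames, conf_frames = [], []
for period in ("trial", "iti"):
    for collapse in ("none", "modality", "environment", "relationship"):
        spec = replace(base, period=period, collapse=collapse)
        announce(f"decoding: period={period} collapse={collapse}")
        res, conf = decode(spikes, trials, schedule, cfg, spec, seed=cfg.rng_seed)
        res_frames.append(res)
        conf_frames.append(conf)

results = pd.concat(res_frames, ignore_index=True)
results.to_csv(RESULTS / "decoding_results.csv", index=False)
pd.concat(conf_frames, ignore_index=True).to_csv(
    RESULTS / "confusion_matrices.csv", index=False)

summary = results.groupby(["period", "collapse"])["accuracy"].agg(["mean", "sem"])
print((100 * summary).round(1).to_string())
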