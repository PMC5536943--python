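#!/usr/bin/env python
"""Ensemble state-vector analyses.

1. Block-pair correlations for trial and ITI epochs (40 r values per
   category), on the default session.
2. The 210 x 210 per-ITI correlation matrix and block-transition similarity
   scores (within vs between, 20 repeats of 100-cell subsamples).
3. The sliding-window trend of transition magnitude across a session-ordered
   139-cell population whose stimulus-environment step grows with experience.
"""

import numpy as np
import pandas as pd

from _common import RESULTS, announce, default_config, load_or_generate
from lecpipe._rng import stage_rng
from lecpipe.ensemble import (
    block_pair_comparison,
    iti_correlation_matrix,
    session_sliding_trend,
    similarity_scores,
)
from lecpipe.synth import GeneratorConfig, PopulationConfig, generate_session

spikes, trials, emg, schedule = load_or_generate()
cfg = default_config()

frames = []
for period in ("trial", "iti"):
    bp = block_pair_comparison(spikes, trials, schedule, cfg, period, seed=cfg.rng_seed)
    bp.insert(0, "period", period)
    frames.append(bp)
blockpair = pd.concat(frames, ignore_index=True)
blockpair.to_csv(RESULTS / "ensemble_blockpair.csv", index=False)
announce("mean r per category (trial epoch):")
print(blockpair[blockpair.period == "trial"].groupby("category")["r"].mean()
      .round(3).to_string())

m = iti_correlation_matrix(spikes, trials, schedule, cfg,
                           stage_rng(cfg.rng_seed, "iti_matrix"))
np.savetxt(RESULTS / "iti_matrix.csv", m, delimiter=",", fmt="%.6g")
announce(f"ITI correlation matrix: {m.shape[0]} x {m.shape[1]}")

sim = similarity_scores(spikes, trials, schedule, cfg, seed=cfg.rng_seed)
sim.to_csv(RESULTS / "similarity_scores.csv", index=False)
announce("similarity scores by transition type:")
print(sim.groupby("type")[["within", "between"]].mean().round(3).to_string())

announce("sliding-window trend on a session-graded 139-cell population")
gen = GeneratorConfig(population=PopulationConfig(
    n_cells=139, rate_median_hz=1.0, effect_size=1.0,
    category_proportions={"M+E": 0.6, "E": 0.2, "R+M+E": 0.2},
    responsive_fraction=0.0, n_sessions=10,
    effect_scale_by_session=tuple(0.2 + 0.12 * i for i in range(10))),
    with_emg=False)
sp2, tr2, _, sch2, _ = generate_session(gen, seed=cfg.rng_seed + 1)
trend = session_sliding_trend(sp2, tr2, sch2, cfg, window=49, step=10,
                              seed=cfg.rng_seed)
trend.to_csv(RESULTS / "trend.csv", index=False)
print(trend.round(4).to_string(index=False))
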