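"""Shared fixtures: compact synthetic sessions generated at test time.

Session fixtures are session-scoped because generation dominates test cost;
tests must not mutate them.
"""

from __future__ import annotations

import numpy as np
import pytest

from lecpipe.synth import CrBehaviorConfig, GeneratorConfig, PopulationConfig, generate_session
from lecpipe.types import AnalysisConfig, BlockSpec, SessionSchedule


def six_block_schedule(n_alone: int, n_paired: int, iti=(10.0, 12.0),
                       emg_rate_hz: float = 10_000.0) -> SessionSchedule:
    """The standard six-block layout with configurable trial counts/ITIs."""
    blocks = []
    bid = 1
    for mod, box in [("auditory", 1), ("auditory", 2), ("visual", 1)]:
        blocks.append(BlockSpec(bid, mod, box, paired=False, n_trials=n_alone))
        blocks.append(BlockSpec(bid + 1, mod, box, paired=True, n_trials=n_paired))
        bid += 2
    return SessionSchedule(blocks=tuple(blocks), iti_min_s=iti[0], iti_max_s=iti[1],
                           emg_rate_hz=emg_rate_hz)


@pytest.fixture(scope="session")
def fast_cfg() -> AnalysisConfig:
    return AnalysisConfig(n_permutations=300, rng_seed=11)


@pytest.fixture(scope="session")
def small_session():
    """24 cells, 6 blocks of 10/12 trials, short ITIs, mixed categories, no EMG."""
    sched = six_block_schedule(10, 12)
    gen = GeneratorConfig(
        schedule=sched,
        population=PopulationConfig(n_cells=24, rate_median_hz=3.0, effect_size=1.0),
        with_emg=False)
    spikes, trials, emg, schedule, truth = generate_session(gen, seed=21)
    return spikes, trials, schedule, truth


@pytest.fixture(scope="session")
def blocked_session():
    """Strong tonic box-keyed population with >= 20 trials per block, for
    similarity-score analyses (within/between windows need 20)."""
    sched = six_block_schedule(20, 25)
    gen = GeneratorConfig(
        schedule=sched,
        population=PopulationConfig(n_cells=40, rate_median_hz=3.0, effect_size=1.0,
                                    category_proportions={"M+E": 1.0},
                                    responsive_fraction=0.0),
        with_emg=False)
    spikes, trials, emg, schedule, truth = generate_session(gen, seed=33)
    return spikes, trials, schedule, truth
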