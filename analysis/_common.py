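"""Shared plumbing for the analysis drivers.

The default session emulates the study conditions: 210 trials in six blocks
(3 x 20 CS-alone + 3 x 50 CS-US), 20-40 s ITIs, 250 cells with the observed
tonic category mix and ~45% phasic responders, 10 kHz EMG with conditioned
responses on ~70% of paired trials.  The session is cached as plain files
under scratch/session so the drivers can run independently.
"""

from __future__ import annotations

import sys
from pathlib import Path

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"
SCRATCH = ROOT / "scratch"
SESSION_DIR = SCRATCH / "session"
SESSION_SEED = 2026

from lecpipe.io import read_session, write_session  # noqa: E402
from lecpipe.synth import GeneratorConfig, generate_session  # noqa: E402
from lecpipe.types import AnalysisConfig  # noqa: E402


def default_config(seed: int = SESSION_SEED) -> AnalysisConfig:
    return AnalysisConfig(rng_seed=seed)


def load_or_generate(with_emg: bool = False):
    """Load the cached default session, or generate (and cache) it."""
    RESULTS.mkdir(exist_ok=True)
    have_emg = (SESSION_DIR / "emg.json").exists()
    if (SESSION_DIR / "schedule.json").exists() and (have_emg or not with_emg):
        spikes, trials, emg, schedule = read_session(SESSION_DIR)
        return spikes, trials, emg, schedule
    gen = GeneratorConfig(with_emg=with_emg)
    spikes, trials, emg, schedule, truth = generate_session(gen, seed=SESSION_SEED)
    SESSION_DIR.mkdir(parents=True, exist_ok=True)
    write_session(SESSION_DIR, spikes, trials, emg, schedule)
    import pandas as pd
    pd.DataFrame([
        {"unit_id": c.unit_id, "category_label": c.category_label,
         "responsive": c.responsive, "layer": c.layer}
        for c in truth["cells"]
    ]).to_csv(SESSION_DIR / "ground_truth_cells.csv", index=False)
    if truth["cr_flags"] is not None:
        pd.Series(truth["cr_flags"], name="cr_true").to_csv(
            SESSION_DIR / "ground_truth_cr.csv", index=False)
    return spikes, trials, emg, schedule


def announce(msg: str) -> None:
    print(f"== {msg}", file=sys.stderr)
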