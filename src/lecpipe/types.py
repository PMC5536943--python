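"""Shared data model for blocked trace eyeblink conditioning sessions.

All event times are in seconds from session start (t = 0); analysis windows
are half-open ``[start, end)``.  Trial indices are 1-based ordinals over the
whole session, so "the 70th trial" means ``trial_index == 70``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "BlockSpec",
    "SessionSchedule",
    "TrialTable",
    "Unit",
    "SpikeTrainSet",
    "EMGTrace",
    "AnalysisConfig",
    "ValidationError",
    "default_blocks",
]

MODALITIES = ("auditory", "visual")
LAYERS = ("superficial", "deep", "unknown")

#: CS onset -> US onset span in seconds (100 ms CS + 500 ms stimulus-free trace)
TRIAL_WINDOW_S = 0.600


class ValidationError(ValueError):
    """Raised when session objects violate a structural invariant."""


@dataclass(frozen=True)
class BlockSpec:
    """One conditioning block: a CS modality in a box, paired with the US or not."""

    block_id: int
    cs_modality: str  # "auditory" | "visual"
    box: int  # 1 | 2
    paired: bool
    n_trials: int

    def __post_init__(self) -> None:
        if self.cs_modality not in MODALITIES:
            raise ValidationError(f"unknown cs_modality {self.cs_modality!r}")
        if self.box not in (1, 2):
            raise ValidationError(f"box must be 1 or 2, got {self.box}")
        if self.n_trials < 1:
            raise ValidationError("n_trials must be >= 1")


def default_blocks() -> list[BlockSpec]:
    """The standard six-block schedule: for each of (auditory CS in box 1,
    auditory CS in box 2, visual CS in box 1), 20 CS-alone trials followed by
    50 CS-US paired trials — 210 trials in total."""
    combos = [("auditory", 1), ("auditory", 2), ("visual", 1)]
    blocks = []
    bid = 1
    for modality, box in combos:
        blocks.append(BlockSpec(bid, modality, box, paired=False, n_trials=20))
        blocks.append(BlockSpec(bid + 1, modality, box, paired=True, n_trials=50))
        bid += 2
    return blocks


@dataclass(frozen=True)
class SessionSchedule:
    """Session-level timing parameters plus the ordered block structure.

    ``iti_min_s``/``iti_max_s`` bound the stimulus-free interval from the end
    of one trial (US offset, or its equivalent on CS-alone trials) to the next
    CS onset.  The 9 s tonic analysis window ends at CS onset, so with the
    default 20 s minimum it always starts >= 11 s after the previous US.
    """

    blocks: tuple[BlockSpec, ...] = field(default_factory=lambda: tuple(default_blocks()))
    iti_min_s: float = 20.0
    iti_max_s: float = 40.0
    cs_duration_s: float = 0.100
    trace_interval_s: float = 0.500
    us_duration_s: float = 0.100
    emg_rate_hz: float = 10_000.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "blocks", tuple(self.blocks))
        if not self.blocks:
            raise ValidationError("schedule needs at least one block")
        ids = [b.block_id for b in self.blocks]
        if len(set(ids)) != len(ids):
            raise ValidationError("block_id values must be unique")
        triples = [(b.cs_modality, b.box, b.paired) for b in self.blocks]
        if len(set(triples)) != len(triples):
            raise ValidationError("(cs_modality, box, paired) must be unique per block")
        if self.iti_min_s > self.iti_max_s:
            raise ValidationError("iti_min_s must be <= iti_max_s")
        window = self.cs_duration_s + self.trace_interval_s
        if self.iti_min_s < 9.0 + window:
            raise ValidationError(
                "iti_min_s must be >= 9 s + trial window so pre-CS windows "
                "never overlap the previous trial"
            )
        if self.emg_rate_hz <= 0:
            raise ValidationError("emg_rate_hz must be positive")

    @property
    def trial_window_s(self) -> float:
        """CS onset -> US onset span (s)."""
        return self.cs_duration_s + self.trace_interval_s

    @property
    def n_trials(self) -> int:
        return sum(b.n_trials for b in self.blocks)

    def block(self, block_id: int) -> BlockSpec:
        for b in self.blocks:
            if b.block_id == block_id:
                return b
        raise KeyError(block_id)


class TrialTable:
    """Per-trial event times as a validated :class:`pandas.DataFrame` wrapper.

    Columns: ``trial_index`` (1-based), ``block_id``, ``cs_onset_s``,
    ``cs_offset_s``, ``us_onset_s`` (NaN on CS-alone trials), and optional
    ``valid`` / ``cr`` annotations filled by the behavior stage.
    """

    REQUIRED = ["trial_index", "block_id", "cs_onset_s", "cs_offset_s", "us_onset_s"]

    def __init__(self, df: pd.DataFrame, schedule: Optional[SessionSchedule] = None):
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise ValidationError(f"trial table missing columns {missing}")
        df = df.reset_index(drop=True).copy()
        idx = df["trial_index"].to_numpy()
        if len(df) and not np.array_equal(idx, np.arange(1, len(df) + 1)):
            raise ValidationError("trial_index must be 1..n in order")
        onsets = df["cs_onset_s"].to_numpy(float)
        if len(df) > 1 and not np.all(np.diff(onsets) > 0):
            raise ValidationError("cs_onset_s must be strictly increasing")
        if schedule is not None:
            for bid, sub in df.groupby("block_id"):
                block = schedule.block(int(bid))
                has_us = np.isfinite(sub["us_onset_s"].to_numpy(float))
                if block.paired and not has_us.all():
                    raise ValidationError(f"paired block {bid} has trials without us_onset_s")
                if not block.paired and has_us.any():
                    raise ValidationError(f"unpaired block {bid} has trials with us_onset_s")
            paired = df["us_onset_s"].notna()
            gap = df.loc[paired, "us_onset_s"] - df.loc[paired, "cs_onset_s"]
            if len(gap) and not np.allclose(gap, schedule.trial_window_s, atol=1e-9):
                raise ValidationError("us_onset_s - cs_onset_s must equal the trial window")
        self.df = df
        self.schedule = schedule

    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TrialTable):
            return NotImplemented
        a = self.df[self.REQUIRED].fillna(-1.0).to_numpy(float)
        b = other.df[self.REQUIRED].fillna(-1.0).to_numpy(float)
        return a.shape == b.shape and np.allclose(a, b, rtol=0, atol=1e-9)

    def block_trials(self, block_id: int) -> pd.DataFrame:
        return self.df[self.df["block_id"] == block_id]

    def us_equivalent_s(self, window: Optional[float] = None) -> np.ndarray:
        """US onset per trial, using the virtual CS onset + 600 ms time on
        CS-alone trials so every trial can be scored the same way."""
        w = TRIAL_WINDOW_S if window is None else window
        us = self.df["us_onset_s"].to_numpy(float).copy()
        nan = ~np.isfinite(us)
        us[nan] = self.df["cs_onset_s"].to_numpy(float)[nan] + w
        return us

    @property
    def end_s(self) -> float:
        if not len(self.df):
            return 0.0
        return float(self.us_equivalent_s().max())


@dataclass
class Unit:
    """One putative single unit with sorted spike times (s)."""

    unit_id: str
    spike_times_s: np.ndarray
    rat_id: str = "sim"
    session_id: str = "sim"
    layer: str = "unknown"

    def __post_init__(self) -> None:
        t = np.asarray(self.spike_times_s, dtype=float)
        if t.ndim != 1:
            raise ValidationError("spike_times_s must be 1-D")
        if len(t) and (np.any(np.diff(t) < 0) or t[0] < 0):
            raise ValidationError(f"unit {self.unit_id}: spike times must be sorted, non-negative")
        if self.layer not in LAYERS:
            raise ValidationError(f"unit {self.unit_id}: unknown layer {self.layer!r}")
        self.spike_times_s = t


class SpikeTrainSet:
    """An ordered collection of units forming a (pseudo-)population."""

    def __init__(self, units: Sequence[Unit]):
        ids = [u.unit_id for u in units]
        if len(set(ids)) != len(ids):
            raise ValidationError("unit_id values must be unique")
        self.units = list(units)

    def __len__(self) -> int:
        return len(self.units)

    def __iter__(self):
        return iter(self.units)

    def __getitem__(self, i: int) -> Unit:
        return self.units[i]

    @property
    def unit_ids(self) -> list[str]:
        return [u.unit_id for u in self.units]

    def subset(self, indices: Sequence[int]) -> "SpikeTrainSet":
        return SpikeTrainSet([self.units[i] for i in indices])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SpikeTrainSet):
            return NotImplemented
        if self.unit_ids != other.unit_ids:
            return False
        return all(
            np.allclose(a.spike_times_s, b.spike_times_s)
            and (a.rat_id, a.session_id, a.layer) == (b.rat_id, b.session_id, b.layer)
            for a, b in zip(self.units, other.units)
        )


@dataclass
class EMGTrace:
    """Continuously sampled eyelid EMG (arbitrary units)."""

    rate_hz: float
    samples: np.ndarray
    t0_s: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise ValidationError("EMG samples must be 1-D")
        if not np.all(np.isfinite(self.samples)):
            raise ValidationError("EMG samples must be finite")
        if self.rate_hz <= 0:
            raise ValidationError("EMG rate must be positive")

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.rate_hz

    def index(self, t_s: float) -> int:
        return int(round((t_s - self.t0_s) * self.rate_hz))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, EMGTrace):
            return NotImplemented
        return (
            self.rate_hz == other.rate_hz
            and self.t0_s == other.t0_s
            and len(self.samples) == len(other.samples)
            and np.allclose(self.samples, other.samples)
        )


@dataclass(frozen=True)
class AnalysisConfig:
    """Knobs shared across analysis stages.

    ``n_permutations`` and ``alpha`` drive every permutation test;
    ``iti_window_s`` is the tonic analysis epoch ending at CS onset;
    the subsample sizes and ``n_repeats`` control the ensemble and decoding
    resampling schemes.
    """

    n_permutations: int = 1000
    alpha: float = 0.05
    iti_window_s: float = 9.0
    pre_cs_window_s: float = 1.0
    n_subsample_cells_ensemble: int = 100
    n_subsample_cells_svm: int = 200
    n_repeats: int = 20
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1):
            raise ValidationError("alpha must be in (0, 1)")
        if self.n_permutations < 1:
            raise ValidationError("n_permutations must be >= 1")
        if self.iti_window_s <= 0 or self.pre_cs_window_s <= 0:
            raise ValidationError("analysis windows must be positive")

    def with_(self, **kw) -> "AnalysisConfig":
        return replace(self, **kw)
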