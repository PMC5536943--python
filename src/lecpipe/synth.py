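"""Synthetic session generator.

Emulates the statistical structure the downstream analyses assume: a fixed
six-block schedule (3 x 20 CS-alone + 3 x 50 CS-US trials; 100 ms CS, 500 ms
trace interval, 20-40 s inter-trial intervals), low-rate Poisson-like spiking
with per-block tonic rate offsets and CS-locked phasic gain, and a 10 kHz
eyelid EMG trace with conditioned-response amplitude bursts in the 200 ms
before US onset on designated trials.

Spiking is piecewise-homogeneous Poisson: the rate is the cell's per-block
baseline outside trial windows and baseline x phasic_gain inside the 600 ms
CS-onset -> US-onset window.  This gives closed-form count oracles (mean count
= rate x duration in any window) for every statistic in scope, all of which
use window-averaged rates.

A cell's selectivity category is built multiplicatively: a cell selective for
a task variable has its rate scaled by (1 + effect_size) in the blocks on its
preferred side of that contrast, with the preferred side (e.g. paired vs
CS-alone for R) drawn at random per cell so that selective populations
re-pattern, not merely re-scale, across blocks.  By construction the set of
block contrasts with unequal generating rates equals exactly the contrasts
implied by the label.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import signal

from .types import (
    BlockSpec,
    EMGTrace,
    SessionSchedule,
    SpikeTrainSet,
    TrialTable,
    Unit,
    ValidationError,
)

__all__ = [
    "CATEGORIES",
    "CellParams",
    "PopulationConfig",
    "CrBehaviorConfig",
    "GeneratorConfig",
    "make_schedule",
    "sample_population",
    "simulate_spikes",
    "simulate_emg",
    "generate_session",
    "category_flags",
]

#: The 8 selectivity categories: combinations of Relationship (CS-alone vs
#: CS-US), Modality (auditory vs visual CS) and Environment (box 1 vs 2).
CATEGORIES = ("Non-S", "R", "M", "E", "R+M", "R+E", "M+E", "R+M+E")

#: Default tonic category mix for a 250-cell pseudo-population, reflecting a
#: regime where nearly every cell carries block information and the triple
#: conjunction dominates.
DEFAULT_CATEGORY_PROPORTIONS = {
    "Non-S": 7 / 250,
    "R": 21 / 250,
    "M": 9 / 250,
    "E": 3 / 250,
    "R+M": 43 / 250,
    "R+E": 35 / 250,
    "M+E": 22 / 250,
    "R+M+E": 110 / 250,
}


def category_flags(label: str) -> tuple[bool, bool, bool]:
    """(R, M, E) selectivity flags implied by a category label."""
    if label == "Non-S":
        return (False, False, False)
    parts = set(label.split("+"))
    if not parts <= {"R", "M", "E"}:
        raise ValidationError(f"unknown category label {label!r}")
    return ("R" in parts, "M" in parts, "E" in parts)


@dataclass
class CellParams:
    """Ground-truth generating parameters for one cell."""

    unit_id: str
    baseline_rate_hz: np.ndarray  # one value per block, schedule order
    phasic_gain: np.ndarray  # multiplicative rate factor in the trial window, per block
    category_label: str
    responsive: bool
    layer: str = "unknown"
    session_order: int = 1

    def __post_init__(self) -> None:
        self.baseline_rate_hz = np.asarray(self.baseline_rate_hz, float)
        self.phasic_gain = np.asarray(self.phasic_gain, float)
        if np.any(self.baseline_rate_hz < 0) or np.any(self.phasic_gain < 0):
            raise ValidationError("rates and gains must be >= 0")
        category_flags(self.category_label)


@dataclass(frozen=True)
class PopulationConfig:
    """Population-level generating parameters.

    ``rate_median_hz``/``rate_sigma`` parameterize the log-normal baseline
    firing-rate distribution (median < 2 Hz, matching the low-rate regime).
    ``effect_size`` is the fractional rate difference for selective contrasts:
    1.0 means the high side of a contrast fires at twice the low side.
    """

    n_cells: int = 250
    category_proportions: dict = field(
        default_factory=lambda: dict(DEFAULT_CATEGORY_PROPORTIONS))
    rate_median_hz: float = 1.0
    rate_sigma: float = 0.6
    effect_size: float = 1.0
    responsive_fraction: float = 0.452
    phasic_gain: float = 3.0
    n_sessions: int = 1
    effect_scale_by_session: Optional[tuple[float, ...]] = None
    within_block_drift: float = 0.0  # fractional linear rate ramp across a block

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValidationError("n_cells must be >= 1")
        total = sum(self.category_proportions.values())
        if not np.isclose(total, 1.0):
            raise ValidationError(f"category proportions must sum to 1, got {total}")
        if any(k not in CATEGORIES for k in self.category_proportions):
            raise ValidationError("unknown category in proportions")
        if self.effect_size <= 0 and any(
                v > 0 for k, v in self.category_proportions.items() if k != "Non-S"):
            raise ValidationError("effect_size must be > 0 with selective categories")


@dataclass(frozen=True)
class CrBehaviorConfig:
    """Conditioned-response behavior of the simulated animal.

    A CR is an EMG amplitude burst of ``cr_burst_amplitude`` x the baseline
    envelope in the 200 ms before (real or virtual) US onset.
    """

    cr_probability_paired: float = 0.7
    cr_probability_alone: float = 0.1
    cr_burst_amplitude: float = 5.0
    cr_window_s: float = 0.200
    baseline_noise_sd: float = 1.0
    band_low_hz: float = 250.0
    band_high_hz: float = 5000.0

    def __post_init__(self) -> None:
        for p in (self.cr_probability_paired, self.cr_probability_alone):
            if not (0.0 <= p <= 1.0):
                raise ValidationError("cr_probability must be in [0, 1]")
        if self.cr_burst_amplitude <= 1.0:
            warnings.warn("cr_burst_amplitude <= 1 is undetectable by construction")

    def probability(self, block: BlockSpec) -> float:
        return self.cr_probability_paired if block.paired else self.cr_probability_alone


@dataclass(frozen=True)
class GeneratorConfig:
    schedule: SessionSchedule = field(default_factory=SessionSchedule)
    population: PopulationConfig = field(default_factory=PopulationConfig)
    behavior: CrBehaviorConfig = field(default_factory=CrBehaviorConfig)
    with_emg: bool = True


def make_schedule(schedule: SessionSchedule, rng: np.random.Generator) -> TrialTable:
    """Lay out trial event times sequentially.

    Each trial is preceded by its own inter-trial interval, drawn uniformly
    from ``[iti_min_s, iti_max_s]`` and measured from the previous trial's US
    offset (or the equivalent virtual time on CS-alone trials) to the next CS
    onset; the first ITI runs from session start.
    """
    rows = []
    t_prev_end = 0.0
    idx = 1
    trial_end = schedule.trial_window_s + schedule.us_duration_s
    for block in schedule.blocks:
        for _ in range(block.n_trials):
            iti = rng.uniform(schedule.iti_min_s, schedule.iti_max_s)
            cs_on = t_prev_end + iti
            us_on = cs_on + schedule.trial_window_s if block.paired else np.nan
            rows.append((idx, block.block_id, cs_on, cs_on + schedule.cs_duration_s, us_on))
            t_prev_end = cs_on + trial_end
            idx += 1
    df = pd.DataFrame(rows, columns=TrialTable.REQUIRED)
    return TrialTable(df, schedule=schedule)


def session_end_s(trials: TrialTable, schedule: SessionSchedule) -> float:
    return trials.end_s + schedule.us_duration_s + 1.0


def sample_population(config: PopulationConfig, rng: np.random.Generator,
                      schedule: SessionSchedule | None = None) -> list[CellParams]:
    """Draw ground-truth cell parameters for a population.

    Categories are drawn i.i.d. from ``category_proportions``; baseline rates
    are log-normal; per-block rates apply the multiplicative selectivity
    construction described in the module docstring.
    """
    schedule = schedule or SessionSchedule()
    labels = list(config.category_proportions)
    probs = np.array([config.category_proportions[k] for k in labels])
    blocks = schedule.blocks
    cells: list[CellParams] = []
    n_sessions = max(1, config.n_sessions)
    per_session = int(np.ceil(config.n_cells / n_sessions))
    for i in range(config.n_cells):
        label = labels[rng.choice(len(labels), p=probs)]
        r_flag, m_flag, e_flag = category_flags(label)
        base = config.rate_median_hz * np.exp(rng.normal(0.0, config.rate_sigma))
        session_order = i // per_session + 1
        eff = config.effect_size
        if config.effect_scale_by_session is not None:
            eff = eff * config.effect_scale_by_session[session_order - 1]
        # preferred side of each contrast, drawn per cell
        pref_r, pref_m, pref_e = rng.random(3) < 0.5

        def _hi(flag: bool, on_high: bool, pref: bool) -> bool:
            return flag and (on_high == pref)

        rates = np.array([
            base
            * (1.0 + eff) ** _hi(r_flag, b.paired, pref_r)
            * (1.0 + eff) ** _hi(m_flag, b.cs_modality == "visual", pref_m)
            * (1.0 + eff) ** _hi(e_flag, b.box == 2, pref_e)
            for b in blocks
        ])
        responsive = bool(rng.random() < config.responsive_fraction)
        gain = np.full(len(blocks), config.phasic_gain if responsive else 1.0)
        layer = "superficial" if rng.random() < 0.5 else "deep"
        cells.append(CellParams(
            unit_id=f"u{i:04d}", baseline_rate_hz=rates, phasic_gain=gain,
            category_label=label, responsive=responsive, layer=layer,
            session_order=session_order))
    return cells


def _segments(cell: CellParams, trials: TrialTable, schedule: SessionSchedule,
              cr_flags: Optional[np.ndarray], cr_gain: float,
              drift: float) -> list[tuple[float, float, float]]:
    """Piecewise-constant rate segments covering [0, session end)."""
    block_index = {b.block_id: i for i, b in enumerate(schedule.blocks)}
    block_sizes = {b.block_id: b.n_trials for b in schedule.blocks}
    segs: list[tuple[float, float, float]] = []
    t_prev = 0.0
    pos_in_block: dict[int, int] = {}
    us_eq = trials.us_equivalent_s(schedule.trial_window_s)
    for i, row in enumerate(trials.df.itertuples(index=False)):
        bi = block_index[row.block_id]
        j = pos_in_block.get(row.block_id, 0)
        pos_in_block[row.block_id] = j + 1
        n_b = block_sizes[row.block_id]
        ramp = 1.0
        if drift and n_b > 1:
            ramp = 1.0 + drift * (j / (n_b - 1) - 0.5)
        base = cell.baseline_rate_hz[bi] * ramp
        trial_rate = base * cell.phasic_gain[bi]
        if cr_flags is not None and cr_flags[i]:
            trial_rate *= cr_gain
        end = us_eq[i] + schedule.us_duration_s
        segs.append((t_prev, row.cs_onset_s, base))  # ITI at tonic rate
        segs.append((row.cs_onset_s, us_eq[i], trial_rate))  # phasic window
        segs.append((us_eq[i], end, base))
        t_prev = end
    return segs


def simulate_spikes(cell: CellParams, trials: TrialTable, rng: np.random.Generator,
                    schedule: SessionSchedule | None = None,
                    cr_flags: Optional[np.ndarray] = None, cr_gain: float = 1.0,
                    drift: float = 0.0) -> np.ndarray:
    """Sample one piecewise-homogeneous Poisson spike train (sorted times, s).

    ``cr_flags``/``cr_gain`` optionally couple the trial-window rate to CR
    expression, for validating the CR-correlation analysis.
    """
    schedule = schedule or trials.schedule or SessionSchedule()
    times = []
    for t0, t1, rate in _segments(cell, trials, schedule, cr_flags, cr_gain, drift):
        dur = t1 - t0
        if dur <= 0 or rate <= 0:
            if rate < 0:
                raise ValidationError("negative rate")
            continue
        n = rng.poisson(rate * dur)
        if n:
            times.append(t0 + rng.random(n) * dur)
    if not times:
        return np.array([])
    return np.sort(np.concatenate(times))


def _bandpass(x: np.ndarray, rate_hz: float, low: float, high: float) -> np.ndarray:
    high = min(high, 0.45 * rate_hz)
    if high <= low:
        raise ValidationError("EMG band edges incompatible with sampling rate")
    sos = signal.butter(4, [low, high], btype="bandpass", fs=rate_hz, output="sos")
    return signal.sosfiltfilt(sos, x)


def simulate_emg(trials: TrialTable, cr_config: CrBehaviorConfig,
                 schedule: SessionSchedule, rng: np.random.Generator,
                 cr_flags: Optional[np.ndarray] = None) -> tuple[EMGTrace, np.ndarray]:
    """Band-limited noise EMG with CR bursts; returns (trace, ground-truth flags).

    On each trial flagged CR (Bernoulli per-block probability unless explicit
    ``cr_flags`` are supplied), the noise amplitude is scaled by
    ``cr_burst_amplitude`` in the ``cr_window_s`` before (virtual) US onset.
    """
    rate = schedule.emg_rate_hz
    n = int(np.ceil(session_end_s(trials, schedule) * rate))
    x = rng.normal(0.0, cr_config.baseline_noise_sd, n)
    x = _bandpass(x, rate, cr_config.band_low_hz, cr_config.band_high_hz)
    if cr_flags is None:
        probs = np.array([
            cr_config.probability(schedule.block(int(b)))
            for b in trials.df["block_id"]
        ])
        cr_flags = rng.random(len(trials)) < probs
    cr_flags = np.asarray(cr_flags, bool)
    us_eq = trials.us_equivalent_s(schedule.trial_window_s)
    for i, flag in enumerate(cr_flags):
        if not flag:
            continue
        hi = int(round(us_eq[i] * rate))
        lo = int(round((us_eq[i] - cr_config.cr_window_s) * rate))
        x[lo:hi] *= cr_config.cr_burst_amplitude
    return EMGTrace(rate_hz=rate, samples=x), cr_flags


def generate_session(config: GeneratorConfig, seed: int = 0):
    """Generate a full session: spikes, trials, EMG (+ ground truth).

    Returns ``(spikes, trials, emg, schedule, truth)`` where ``truth`` carries
    the generating :class:`CellParams` and per-trial CR flags.
    """
    from ._rng import stage_rng

    sched = config.schedule
    trials = make_schedule(sched, stage_rng(seed, "schedule"))
    cells = sample_population(config.population, stage_rng(seed, "population"), sched)
    spike_rng = stage_rng(seed, "spikes")
    drift = config.population.within_block_drift
    units = [
        Unit(c.unit_id, simulate_spikes(c, trials, spike_rng, sched, drift=drift),
             rat_id=f"r{(c.session_order - 1) % 7 + 1}",
             session_id=f"s{c.session_order:02d}", layer=c.layer)
        for c in cells
    ]
    spikes = SpikeTrainSet(units)
    emg = cr_flags = None
    if config.with_emg:
        emg, cr_flags = simulate_emg(trials, config.behavior, sched, stage_rng(seed, "emg"))
    truth = {"cells": cells, "cr_flags": cr_flags}
    return spikes, trials, emg, sched, truth
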