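"""Per-unit selectivity, responsiveness, stability and CR-correlation statistics.

Three analysis epochs per trial, all half-open and ending on trial events:

* trial window  — CS onset to US onset (600 ms), the phasic epoch
* pre-CS window — 1 s before CS onset (responsiveness baseline)
* ITI window    — 9 s before CS onset, the tonic epoch; with inter-trial
  intervals of at least 20 s it always starts >= 11 s after the previous US
  offset, avoiding lingering post-US rate changes

Selectivity between two trial conditions is the differential index

    DI = |Fr1 - Fr2| / (Fr1 + Fr2)        in [0, 1]

shuffle-corrected by subtracting the upper ``1 - alpha`` quantile of the DI
distribution under random relabeling of trials; a unit is selective iff the
corrected DI is positive.  CS-responsiveness uses the analogous permutation
test on |mean trial-window rate - mean pre-CS rate| where the null swaps the
two epoch rates within each trial.  For small trial counts both nulls can be
enumerated exhaustively instead of sampled.

Task-variable contrasts (R = CS-alone vs CS-US within a modality/box pair,
any of the three pairs; M = auditory vs visual CS in box 1, CS-alone and
CS-US trials pooled; E = auditory CS in box 1 vs box 2, pooled) combine into
an 8-way category label per epoch.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import ceil, comb
from typing import Optional

import numpy as np
import pandas as pd
from scipy.special import rel_entr

from ._rng import stage_rng
from .types import AnalysisConfig, SessionSchedule, SpikeTrainSet, TrialTable, Unit, ValidationError
from .synth import CATEGORIES

__all__ = [
    "window_rate",
    "window_rates",
    "differential_index",
    "shuffle_corrected_di",
    "cs_responsive_test",
    "DiResult",
    "PermTestResult",
    "classify_unit",
    "selectivity_table",
    "bin_size_sweep",
    "kld",
    "stability_klds",
    "stability_table",
    "cr_correlation",
    "cr_correlation_table",
    "contrast_blocks",
]

_LN2 = np.log(2.0)
_EXACT_LIMIT = 20  # max trials per condition for exhaustive nulls


# ---------------------------------------------------------------------------
# rates

def window_rate(spike_times_s: np.ndarray, start_s: float, end_s: float) -> float:
    """Spike count in the half-open window [start, end) divided by its length."""
    if end_s <= start_s:
        raise ValidationError("zero or negative-length window")
    t = np.asarray(spike_times_s)
    n = np.searchsorted(t, end_s, side="left") - np.searchsorted(t, start_s, side="left")
    return float(n) / (end_s - start_s)


def window_rates(spike_times_s: np.ndarray, starts: np.ndarray, ends: np.ndarray) -> np.ndarray:
    """Vectorized :func:`window_rate` over many windows."""
    t = np.asarray(spike_times_s)
    starts = np.asarray(starts, float)
    ends = np.asarray(ends, float)
    if np.any(ends <= starts):
        raise ValidationError("zero or negative-length window")
    counts = np.searchsorted(t, ends, side="left") - np.searchsorted(t, starts, side="left")
    return counts / (ends - starts)


def epoch_rates(unit: Unit, trials: TrialTable, schedule: SessionSchedule,
                config: AnalysisConfig) -> dict[str, np.ndarray]:
    """Per-trial rates in the trial, pre-CS and ITI epochs."""
    cs_on = trials.df["cs_onset_s"].to_numpy(float)
    us_eq = trials.us_equivalent_s(schedule.trial_window_s)
    t = unit.spike_times_s
    return {
        "trial": window_rates(t, cs_on, us_eq),
        "pre_cs": window_rates(t, cs_on - config.pre_cs_window_s, cs_on),
        "iti": window_rates(t, cs_on - config.iti_window_s, cs_on),
    }


# ---------------------------------------------------------------------------
# differential index and permutation machinery

def differential_index(fr1: float, fr2: float) -> float:
    """|fr1 - fr2| / (fr1 + fr2); NaN (undefined) when both rates are zero."""
    if fr1 < 0 or fr2 < 0:
        raise ValidationError("rates must be non-negative")
    denom = fr1 + fr2
    if denom == 0:
        return np.nan
    return abs(fr1 - fr2) / denom


def _upper_quantile(null: np.ndarray, alpha: float) -> float:
    """The ceil((1-alpha) * n)-th order statistic of the null sample."""
    srt = np.sort(null)
    k = ceil((1.0 - alpha) * len(srt))
    return float(srt[max(k - 1, 0)])


@dataclass
class DiResult:
    di_raw: float
    di_corrected: float
    selective: bool
    threshold: float
    n_null: int


def _di_null_permutation(pooled: np.ndarray, n_a: int, n_shuffles: int,
                         rng: np.random.Generator) -> np.ndarray:
    mats = rng.permuted(np.broadcast_to(pooled, (n_shuffles, len(pooled))).copy(), axis=1)
    m_a = mats[:, :n_a].mean(axis=1)
    m_b = mats[:, n_a:].mean(axis=1)
    denom = m_a + m_b
    with np.errstate(invalid="ignore"):
        return np.abs(m_a - m_b) / denom


def _di_null_exact(pooled: np.ndarray, n_a: int) -> np.ndarray:
    n = len(pooled)
    total = pooled.sum()
    out = np.empty(comb(n, n_a))
    for i, idx in enumerate(combinations(range(n), n_a)):
        s_a = pooled[list(idx)].sum()
        m_a = s_a / n_a
        m_b = (total - s_a) / (n - n_a)
        denom = m_a + m_b
        out[i] = np.abs(m_a - m_b) / denom if denom else np.nan
    return out


def shuffle_corrected_di(rates_a: np.ndarray, rates_b: np.ndarray,
                         n_shuffles: int = 1000, alpha: float = 0.05,
                         rng: Optional[np.random.Generator] = None,
                         exact: bool = False) -> DiResult:
    """Shuffle-corrected differential index between two trial conditions.

    ``di_corrected = di_raw - q`` where ``q`` is the upper ``1 - alpha``
    quantile of DIs computed after randomly permuting the condition labels
    (``n_shuffles`` draws, or every label assignment when ``exact``).
    Selective iff ``di_corrected > 0``.  All-zero rates in both conditions
    leave the DI undefined (NaN, not selective).
    """
    a = np.asarray(rates_a, float)
    b = np.asarray(rates_b, float)
    if len(a) == 0 or len(b) == 0:
        raise ValidationError("both conditions need at least one trial")
    di_raw = differential_index(a.mean(), b.mean())
    if np.isnan(di_raw):
        return DiResult(np.nan, np.nan, False, np.nan, 0)
    pooled = np.concatenate([a, b])
    if exact:
        if len(a) > _EXACT_LIMIT or len(pooled) > 2 * _EXACT_LIMIT:
            raise ValidationError("exact enumeration limited to small trial counts")
        null = _di_null_exact(pooled, len(a))
    else:
        null = _di_null_permutation(pooled, len(a), n_shuffles, rng or np.random.default_rng())
    null = null[np.isfinite(null)]
    thr = _upper_quantile(null, alpha)
    corrected = di_raw - thr
    return DiResult(di_raw, corrected, bool(corrected > 0), thr, len(null))


@dataclass
class PermTestResult:
    statistic: float
    threshold: float
    p_estimate: float
    significant: bool


def cs_responsive_test(trial_rates: np.ndarray, pre_rates: np.ndarray,
                       n_perm: int = 1000, alpha: float = 0.05,
                       rng: Optional[np.random.Generator] = None,
                       exact: bool = False) -> PermTestResult:
    """Permutation test for a firing-rate change between the trial window and
    the pre-CS window.

    Statistic: |mean trial rate - mean pre-CS rate|.  The null randomly
    re-assigns, per trial, the two epoch rates to the two epoch labels, which
    flips the sign of that trial's rate difference.  Significant iff the
    observed statistic exceeds the upper ``1 - alpha`` null quantile.
    """
    tr = np.asarray(trial_rates, float)
    pre = np.asarray(pre_rates, float)
    if len(tr) != len(pre) or len(tr) < 2:
        raise ValidationError("need matched trial/pre-CS rates for >= 2 trials")
    if n_perm < 1.0 / alpha:
        import warnings
        warnings.warn("n_perm < 1/alpha: permutation resolution insufficient")
    d = tr - pre
    stat = abs(d.mean())
    n = len(d)
    if exact:
        if n > _EXACT_LIMIT:
            raise ValidationError("exact enumeration limited to small trial counts")
        signs = np.array(np.meshgrid(*([[-1.0, 1.0]] * n))).reshape(n, -1).T
        null = np.abs(signs @ d) / n
    else:
        rng = rng or np.random.default_rng()
        signs = rng.integers(0, 2, size=(n_perm, n)) * 2.0 - 1.0
        null = np.abs(signs @ d) / n
    thr = _upper_quantile(null, alpha)
    p = (1.0 + np.sum(null >= stat)) / (len(null) + 1.0)
    return PermTestResult(stat, thr, float(p), bool(stat > thr))


# ---------------------------------------------------------------------------
# task-variable contrasts and 8-way classification

def contrast_blocks(schedule: SessionSchedule) -> dict[str, list[tuple[list[int], list[int]]]]:
    """Block-id groupings for the R / M / E contrasts.

    R: one (alone, paired) pair per (modality, box) combination.
    M: auditory-in-box-1 blocks (alone + paired pooled) vs visual-in-box-1.
    E: auditory-in-box-1 vs auditory-in-box-2, pooled likewise.
    Contrasts whose blocks are absent from the schedule are omitted.
    """
    by_combo: dict[tuple[str, int], dict[bool, int]] = {}
    for b in schedule.blocks:
        by_combo.setdefault((b.cs_modality, b.box), {})[b.paired] = b.block_id
    out: dict[str, list[tuple[list[int], list[int]]]] = {"R": [], "M": [], "E": []}
    for combo, d in by_combo.items():
        if False in d and True in d:
            out["R"].append(([d[False]], [d[True]]))
    a1 = by_combo.get(("auditory", 1), {})
    v1 = by_combo.get(("visual", 1), {})
    a2 = by_combo.get(("auditory", 2), {})
    if a1 and v1:
        out["M"].append((sorted(a1.values()), sorted(v1.values())))
    if a1 and a2:
        out["E"].append((sorted(a1.values()), sorted(a2.values())))
    return {k: v for k, v in out.items() if v}


def _category_from_flags(r: Optional[bool], m: Optional[bool], e: Optional[bool]) -> str:
    parts = [name for name, flag in (("R", r), ("M", m), ("E", e)) if flag]
    return "+".join(parts) if parts else "Non-S"


def classify_unit(rates: np.ndarray, block_ids: np.ndarray, schedule: SessionSchedule,
                  config: AnalysisConfig, rng: np.random.Generator) -> dict:
    """Classify one epoch's per-trial rates into the 8-way selectivity category.

    Returns flags and the max |shuffle-corrected DI| per contrast.  The R flag
    is raised if any of the three alone-vs-paired block pairs is selective.
    """
    contrasts = contrast_blocks(schedule)
    flags: dict[str, Optional[bool]] = {}
    di_raw: dict[str, float] = {}
    di_corr: dict[str, float] = {}
    for name, pairs in contrasts.items():
        best: Optional[DiResult] = None
        any_defined = False
        for grp_a, grp_b in pairs:
            ra = rates[np.isin(block_ids, grp_a)]
            rb = rates[np.isin(block_ids, grp_b)]
            if len(ra) == 0 or len(rb) == 0:
                continue
            res = shuffle_corrected_di(ra, rb, config.n_permutations, config.alpha, rng)
            if np.isnan(res.di_raw):
                continue
            any_defined = True
            if best is None or res.di_corrected > best.di_corrected:
                best = res
        if not any_defined or best is None:
            flags[name] = None
            di_raw[name] = np.nan
            di_corr[name] = np.nan
        else:
            flags[name] = best.selective
            di_raw[name] = best.di_raw
            di_corr[name] = best.di_corrected
    return {
        "flags": flags,
        "di_raw": di_raw,
        "di_corrected": di_corr,
        "category": _category_from_flags(flags.get("R"), flags.get("M"), flags.get("E")),
    }


def selectivity_table(spikes: SpikeTrainSet, trials: TrialTable,
                      schedule: SessionSchedule, config: AnalysisConfig,
                      seed: int = 0) -> pd.DataFrame:
    """Full per-unit selectivity table over both epochs.

    One row per unit: per-block responsiveness verdicts collapsed to a single
    ``responsive`` flag (significant in >= 1 of the blocks), then for each of
    the trial and ITI epochs the R/M/E flags, DI values and category label.
    """
    rng = stage_rng(seed, "selectivity")
    rows = []
    block_ids = trials.df["block_id"].to_numpy()
    for unit in spikes:
        er = epoch_rates(unit, trials, schedule, config)
        sig_blocks = []
        for b in schedule.blocks:
            m = block_ids == b.block_id
            if m.sum() < 2:
                continue
            res = cs_responsive_test(er["trial"][m], er["pre_cs"][m],
                                     config.n_permutations, config.alpha, rng)
            if res.significant:
                sig_blocks.append(b.block_id)
        row = {
            "unit_id": unit.unit_id,
            "layer": unit.layer,
            "responsive": bool(sig_blocks),
            "n_responsive_blocks": len(sig_blocks),
        }
        for period, key in (("trial", "trial"), ("iti", "iti")):
            cls = classify_unit(er[key], block_ids, schedule, config, rng)
            row[f"category_{period}"] = cls["category"]
            for c in ("R", "M", "E"):
                row[f"{period}_{c}_selective"] = cls["flags"].get(c)
                row[f"{period}_di_raw_{c}"] = cls["di_raw"].get(c, np.nan)
                row[f"{period}_di_corrected_{c}"] = cls["di_corrected"].get(c, np.nan)
        rows.append(row)
    return pd.DataFrame(rows)


def category_counts(table: pd.DataFrame, period: str = "iti") -> pd.DataFrame:
    """Category count/percentage summary (overall and by layer)."""
    col = f"category_{period}"
    out = []
    groups = [("all", table)] + [(lyr, table[table["layer"] == lyr])
                                 for lyr in sorted(table["layer"].unique())]
    for name, sub in groups:
        counts = sub[col].value_counts()
        row = {"group": name, "n": len(sub)}
        for cat in CATEGORIES:
            c = int(counts.get(cat, 0))
            row[cat] = c
            row[f"{cat}_pct"] = 100.0 * c / len(sub) if len(sub) else np.nan
        out.append(row)
    return pd.DataFrame(out)


def bin_size_sweep(spikes: SpikeTrainSet, trials: TrialTable, schedule: SessionSchedule,
                   config: AnalysisConfig, partitions: tuple[int, ...] = (1, 4, 8),
                   seed: int = 0) -> pd.DataFrame:
    """Re-run the ITI selectivity criteria at several temporal partitions.

    The 9 s ITI is split into 1, 4 or 8 equal bins; rates are re-estimated per
    bin and the full R/M/E classification re-applied per bin.  Returns one row
    per (unit, partition, bin) with the selective-or-not verdict and category;
    the expected pattern on low-rate data is a shrinking selective fraction as
    bins shorten (noisier rate estimates), not a change in the code itself.
    """
    rng = stage_rng(seed, "bin_sweep")
    cs_on = trials.df["cs_onset_s"].to_numpy(float)
    block_ids = trials.df["block_id"].to_numpy()
    rows = []
    for unit in spikes:
        for k in partitions:
            edges = np.linspace(-config.iti_window_s, 0.0, k + 1)
            for j in range(k):
                rates = window_rates(unit.spike_times_s, cs_on + edges[j], cs_on + edges[j + 1])
                cls = classify_unit(rates, block_ids, schedule, config, rng)
                selective = any(bool(v) for v in cls["flags"].values())
                rows.append({
                    "unit_id": unit.unit_id, "partition": k, "bin": j + 1,
                    "selective": selective, "category": cls["category"],
                })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# firing-rate stability (Kullback-Leibler divergence)

def kld(p: np.ndarray, q: np.ndarray) -> float:
    """D_KL(P || Q) in bits; P(i) = 0 terms contribute 0, Q must be > 0."""
    p = np.asarray(p, float)
    q = np.asarray(q, float)
    if p.shape != q.shape:
        raise ValidationError("P and Q must have the same length")
    if np.any(q <= 0):
        raise ValidationError("Q must be strictly positive")
    if not (np.isclose(p.sum(), 1.0) and np.isclose(q.sum(), 1.0)):
        raise ValidationError("P and Q must sum to 1")
    if np.any(p < 0):
        raise ValidationError("P must be non-negative")
    return float(rel_entr(p, q).sum() / _LN2)


@dataclass
class StabilityResult:
    unit_id: str
    within_kld: float
    between_kld: float
    kld_difference: float
    n_within_defined: int
    n_between_defined: int


def stability_klds(unit: Unit, trials: TrialTable, schedule: SessionSchedule,
                   config: AnalysisConfig, n_bins: int = 15) -> StabilityResult:
    """Within- vs between-block ITI firing stability for one unit.

    The 9 s ITI is split into fifteen 600 ms bins and trial-averaged per
    block.  Within-block divergence: per block, the 15-bin profile normalized
    to sum 1 against uniform-15 (median over blocks).  Between-block: per time
    bin, the rate vector across blocks normalized to sum 1 against uniform
    over blocks (median over bins).  All-zero profiles are undefined and
    excluded from the medians.
    """
    cs_on = trials.df["cs_onset_s"].to_numpy(float)
    block_ids = trials.df["block_id"].to_numpy()
    edges = np.linspace(-config.iti_window_s, 0.0, n_bins + 1)
    blocks = [b.block_id for b in schedule.blocks]
    profile = np.zeros((len(blocks), n_bins))
    for bi, bid in enumerate(blocks):
        m = block_ids == bid
        if not m.any():
            profile[bi] = np.nan
            continue
        for j in range(n_bins):
            profile[bi, j] = window_rates(
                unit.spike_times_s, cs_on[m] + edges[j], cs_on[m] + edges[j + 1]).mean()

    within = []
    u_bins = np.full(n_bins, 1.0 / n_bins)
    for bi in range(len(blocks)):
        row = profile[bi]
        s = row.sum()
        if not np.isfinite(s) or s <= 0:
            continue
        within.append(kld(row / s, u_bins))
    between = []
    u_blocks = np.full(len(blocks), 1.0 / len(blocks))
    for j in range(n_bins):
        col = profile[:, j]
        if not np.all(np.isfinite(col)):
            continue
        s = col.sum()
        if s <= 0:
            continue
        between.append(kld(col / s, u_blocks))
    w = float(np.median(within)) if within else np.nan
    b = float(np.median(between)) if between else np.nan
    return StabilityResult(unit.unit_id, w, b, b - w, len(within), len(between))


def stability_table(spikes: SpikeTrainSet, trials: TrialTable, schedule: SessionSchedule,
                    config: AnalysisConfig) -> pd.DataFrame:
    rows = [stability_klds(u, trials, schedule, config) for u in spikes]
    return pd.DataFrame([r.__dict__ for r in rows])


# ---------------------------------------------------------------------------
# correlation with CR expression

@dataclass
class CrCorrelationResult:
    unit_id: str
    block_id: int
    computable: bool
    n_cr_trials: int
    n_noncr_trials: int
    di_trial: float = np.nan
    selective_trial: bool = False
    di_iti: float = np.nan
    selective_iti: bool = False


def cr_correlation(unit: Unit, trials: TrialTable, cr_labels: np.ndarray,
                   block_id: int, schedule: SessionSchedule, config: AnalysisConfig,
                   rng: np.random.Generator, min_trials: int = 20) -> CrCorrelationResult:
    """DI between CR and non-CR trials of one CS-US block (trial + ITI epochs).

    Requires at least ``min_trials`` of each type; ``min_trials`` are sampled
    from each without replacement to match counts, then the usual
    shuffle-corrected DI machinery is applied.
    """
    m = trials.df["block_id"].to_numpy() == block_id
    labels = np.asarray(cr_labels)[m]
    cr_idx = np.flatnonzero(labels == "CR")
    non_idx = np.flatnonzero(labels == "noCR")
    res = CrCorrelationResult(unit.unit_id, block_id, False, len(cr_idx), len(non_idx))
    if len(cr_idx) < min_trials or len(non_idx) < min_trials:
        return res
    take_cr = rng.choice(cr_idx, size=min_trials, replace=False)
    take_non = rng.choice(non_idx, size=min_trials, replace=False)
    er = epoch_rates(unit, trials, schedule, config)
    res.computable = True
    for period in ("trial", "iti"):
        rates = er[period][m]
        di = shuffle_corrected_di(rates[take_cr], rates[take_non],
                                  config.n_permutations, config.alpha, rng)
        setattr(res, f"di_{period}", di.di_corrected)
        setattr(res, f"selective_{period}", di.selective)
    return res


def cr_correlation_table(spikes: SpikeTrainSet, trials: TrialTable, cr_labels: np.ndarray,
                         schedule: SessionSchedule, config: AnalysisConfig,
                         seed: int = 0) -> pd.DataFrame:
    rng = stage_rng(seed, "cr_correlation")
    rows = []
    for unit in spikes:
        for b in schedule.blocks:
            if not b.paired:
                continue
            rows.append(cr_correlation(unit, trials, cr_labels, b.block_id,
                                       schedule, config, rng).__dict__)
    return pd.DataFrame(rows)
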