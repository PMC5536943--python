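"""Ensemble state-vector analyses.

A state vector is the vector of per-cell firing rates at one trial (600 ms
CS-onset -> US-onset window) or one inter-trial interval (9 s pre-CS window,
or a random 600 ms bin within it).  Cells recorded in different sessions are
aligned by within-session trial index (pseudo-population; inter-cell
correlations are ignored by construction).  Firing rates are normalized per
cell by that cell's maximum over the declared scope; cells with an all-zero
scope are dropped from the analysis.

Three analyses:

* block-pair comparison — per repeat, average 10 random per-trial vectors per
  block and correlate block pairs grouped by which task variable differs
  (Modality / Environment / Relationship / None / All), 2 pairs x 20 repeats
  = 40 r values per category;
* ITI correlation matrix — all-pairs Pearson r of per-ITI state vectors
  (210 x 210 on the default schedule) from a random cell subsample;
* similarity scores — for each block transition, mean r between the last ITI
  of a block (template) and the 19 ITIs before it (within) or the first 19
  ITIs of the next block (between), resampled over cell subsets; plus an OLS
  trend of (within - between) across a sliding window of session-ordered
  cells.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._rng import stage_rng
from .selectivity import window_rates
from .types import AnalysisConfig, SessionSchedule, SpikeTrainSet, TrialTable, ValidationError

__all__ = [
    "pearson_r",
    "normalize_rows",
    "state_vectors",
    "block_pair_comparison",
    "iti_correlation_matrix",
    "similarity_scores",
    "similarity_scores_from_matrix",
    "session_sliding_trend",
    "transition_type",
]

PAIR_CATEGORIES = ("Modality", "Environment", "Relationship", "None", "All")


def pearson_r(x: np.ndarray, y: np.ndarray) -> float:
    """Product-moment correlation; NaN (with a warning) for constant input."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValidationError("pearson_r needs two equal-length vectors of >= 3 samples")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("constant vector: correlation undefined")
        return np.nan
    return float(np.corrcoef(x, y)[0, 1])


def normalize_rows(m: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Divide each row (cell) by its max; drops all-zero rows.

    Returns (normalized matrix, boolean mask of kept rows).  Idempotent on
    already-normalized input.
    """
    m = np.asarray(m, float)
    mx = m.max(axis=1)
    keep = mx > 0
    return m[keep] / mx[keep, None], keep


def state_vectors(spikes: SpikeTrainSet, starts: np.ndarray, ends: np.ndarray) -> np.ndarray:
    """cells x windows matrix of raw rates."""
    return np.vstack([window_rates(u.spike_times_s, starts, ends) for u in spikes])


def _iti_bin_windows(trials: TrialTable, config: AnalysisConfig, window_s: float,
                     rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """One random 600 ms bin per trial, inside the 9 s pre-CS window."""
    cs_on = trials.df["cs_onset_s"].to_numpy(float)
    lo = cs_on - config.iti_window_s
    offs = rng.uniform(0.0, config.iti_window_s - window_s, size=len(cs_on))
    return lo + offs, lo + offs + window_s


def _category_pairs(schedule: SessionSchedule) -> dict[str, list]:
    """The block pairs compared per category, in schedule block-id terms.

    "None" entries are (block_id, block_id) pairs resolved odd-vs-even at
    comparison time.
    """
    def bid(modality, box, paired):
        for b in schedule.blocks:
            if (b.cs_modality, b.box, b.paired) == (modality, box, paired):
                return b.block_id
        raise ValidationError("schedule lacks the block structure for pair comparisons")

    a1a, a1p = bid("auditory", 1, False), bid("auditory", 1, True)
    a2a, a2p = bid("auditory", 2, False), bid("auditory", 2, True)
    v1a, v1p = bid("visual", 1, False), bid("visual", 1, True)
    return {
        "Modality": [(a1a, v1a), (a1p, v1p)],
        "Environment": [(a1a, a2a), (a1p, a2p)],
        "Relationship": [(a1a, a1p), (v1a, v1p)],
        "None": [(a1p, a1p), (v1p, v1p)],
        "All": [(a2a, v1p), (a2p, v1a)],
    }


def block_pair_comparison(spikes: SpikeTrainSet, trials: TrialTable,
                          schedule: SessionSchedule, config: AnalysisConfig,
                          period: str = "trial", seed: int = 0,
                          n_select: int = 10) -> pd.DataFrame:
    """Ensemble similarity between block pairs grouped by differing variable.

    Per repeat: average ``n_select`` randomly chosen per-trial state vectors
    per block, normalize each cell by its max across the six averaged
    vectors, then correlate the category's block pairs.  "None" compares
    averages of odd- vs even-numbered trials of the same block (upper bound);
    "All" compares blocks sharing no task variable (lower bound).  ITI-period
    vectors use a fresh random 600 ms bin per trial each repeat.

    Returns a tidy frame (category, repeat, pair, r): 2 pairs x ``n_repeats``
    repeats = 40 rows per category at defaults.
    """
    if period not in ("trial", "iti"):
        raise ValidationError("period must be 'trial' or 'iti'")
    rng = stage_rng(seed, f"blockpair_{period}")
    pairs = _category_pairs(schedule)
    df = trials.df
    cs_on = df["cs_onset_s"].to_numpy(float)
    us_eq = trials.us_equivalent_s(schedule.trial_window_s)
    block_ids = df["block_id"].to_numpy()
    trial_pos = df.groupby("block_id").cumcount().to_numpy() + 1  # 1-based within block

    block_trial_idx = {b.block_id: np.flatnonzero(block_ids == b.block_id) for b in schedule.blocks}
    for b in schedule.blocks:
        if len(block_trial_idx[b.block_id]) < n_select:
            raise ValidationError(f"block {b.block_id} has fewer than {n_select} trials")

    rows = []
    for rep in range(config.n_repeats):
        if period == "trial":
            sv = state_vectors(spikes, cs_on, us_eq)
        else:
            lo, hi = _iti_bin_windows(trials, config, schedule.trial_window_s, rng)
            sv = state_vectors(spikes, lo, hi)

        block_vec = {}
        for bid_, idx in block_trial_idx.items():
            take = rng.choice(idx, size=n_select, replace=False)
            block_vec[bid_] = sv[:, take].mean(axis=1)
        six = np.column_stack([block_vec[b.block_id] for b in schedule.blocks])
        mx = six.max(axis=1)
        keep = mx > 0
        denom = mx[keep, None]

        def norm(vec: np.ndarray) -> np.ndarray:
            return vec[keep] / denom[:, 0]

        for cat, plist in pairs.items():
            for pi, (b1, b2) in enumerate(plist):
                if cat == "None":
                    idx = block_trial_idx[b1]
                    odd = idx[trial_pos[idx] % 2 == 1]
                    even = idx[trial_pos[idx] % 2 == 0]
                    v1 = sv[:, rng.choice(odd, size=min(n_select, len(odd)), replace=False)].mean(axis=1)
                    v2 = sv[:, rng.choice(even, size=min(n_select, len(even)), replace=False)].mean(axis=1)
                    r = pearson_r(norm(v1), norm(v2))
                else:
                    r = pearson_r(norm(block_vec[b1]), norm(block_vec[b2]))
                rows.append({"category": cat, "repeat": rep + 1, "pair": pi + 1, "r": r})
    return pd.DataFrame(rows)


def iti_correlation_matrix(spikes: SpikeTrainSet, trials: TrialTable,
                           schedule: SessionSchedule, config: AnalysisConfig,
                           rng: np.random.Generator | None = None,
                           n_subsample: int | None = None) -> np.ndarray:
    """All-pairs Pearson matrix of per-ITI state vectors (n_trials square).

    Subsamples ``n_subsample`` cells (default from config) without
    replacement, builds the 9 s mean-rate vector per ITI, normalizes each
    cell by its max across all ITIs, and correlates every ITI pair.
    """
    rng = rng or np.random.default_rng()
    n_sub = n_subsample if n_subsample is not None else config.n_subsample_cells_ensemble
    if len(spikes) > n_sub:
        take = rng.choice(len(spikes), size=n_sub, replace=False)
        spikes = spikes.subset(sorted(take))
    cs_on = trials.df["cs_onset_s"].to_numpy(float)
    sv = state_vectors(spikes, cs_on - config.iti_window_s, cs_on)
    norm, _ = normalize_rows(sv)
    if norm.shape[0] < 2:
        raise ValidationError("too few active cells for a correlation matrix")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return np.corrcoef(norm, rowvar=False)


def transition_type(earlier, later) -> str:
    """Label a block transition by what changes: R (contingency), E
    (environment), E+M (environment + modality), or M."""
    changes = []
    if earlier.box != later.box:
        changes.append("E")
    if earlier.cs_modality != later.cs_modality:
        changes.append("M")
    if not changes:
        return "R"
    return "+".join(changes)


def similarity_scores_from_matrix(matrix: np.ndarray, schedule: SessionSchedule,
                                  n_compare: int = 19) -> pd.DataFrame:
    """Within/between-block similarity scores from one ITI correlation matrix.

    Template = last ITI of each non-final block.  Within score: mean r with
    the ``n_compare`` ITIs immediately preceding the template; between score:
    mean r with the first ``n_compare`` ITIs of the following block.
    """
    sizes = [b.n_trials for b in schedule.blocks]
    if any(s < n_compare + 1 for s in sizes):
        raise ValidationError(f"every block needs > {n_compare} trials")
    bounds = np.cumsum([0] + sizes)
    rows = []
    for i in range(len(sizes) - 1):
        tmpl = bounds[i + 1] - 1  # last ITI of block i (0-based)
        within_idx = np.arange(tmpl - n_compare, tmpl)
        between_idx = np.arange(bounds[i + 1], bounds[i + 1] + n_compare)
        rows.append({
            "transition": i + 1,
            "type": transition_type(schedule.blocks[i], schedule.blocks[i + 1]),
            "template_trial": tmpl + 1,
            "within": float(np.nanmean(matrix[tmpl, within_idx])),
            "between": float(np.nanmean(matrix[tmpl, between_idx])),
        })
    return pd.DataFrame(rows)


def similarity_scores(spikes: SpikeTrainSet, trials: TrialTable, schedule: SessionSchedule,
                      config: AnalysisConfig, seed: int = 0,
                      n_repeats: int | None = None,
                      n_subsample: int | None = None) -> pd.DataFrame:
    """Similarity scores resampled over random cell subsets.

    Returns one row per (repeat, transition) with within/between scores.
    """
    rng = stage_rng(seed, "similarity")
    n_rep = n_repeats if n_repeats is not None else config.n_repeats
    out = []
    for rep in range(n_rep):
        m = iti_correlation_matrix(spikes, trials, schedule, config, rng, n_subsample)
        scores = similarity_scores_from_matrix(m, schedule)
        scores.insert(0, "repeat", rep + 1)
        out.append(scores)
    return pd.concat(out, ignore_index=True)


@dataclass
class TrendResult:
    transition_type: str
    slope: float
    r_squared: float
    p_value: float
    n_windows: int


def session_sliding_trend(spikes: SpikeTrainSet, trials: TrialTable,
                          schedule: SessionSchedule, config: AnalysisConfig,
                          window: int = 49, step: int = 10,
                          seed: int = 0) -> pd.DataFrame:
    """OLS trend of (within - between) similarity across session-ordered cells.

    Units must carry session order in ``session_id`` (sorted lexically).
    A sliding window of ``window`` cells advanced by ``step`` approximates a
    sliding block of sessions; per window the similarity-score difference is
    computed per transition type and regressed on window index.
    """
    units = sorted(spikes, key=lambda u: u.session_id)
    if len(units) < window:
        raise ValidationError("fewer cells than one sliding window")
    rng = stage_rng(seed, "sliding_trend")
    diffs: dict[str, list] = {}
    starts = list(range(0, len(units) - window + 1, step))
    for w, lo in enumerate(starts):
        sub = SpikeTrainSet(units[lo:lo + window])
        m = iti_correlation_matrix(sub, trials, schedule, config, rng, n_subsample=window)
        scores = similarity_scores_from_matrix(m, schedule)
        for ttype, grp in scores.groupby("type"):
            diffs.setdefault(ttype, []).append(float((grp["within"] - grp["between"]).mean()))
    rows = [fit_trend(ttype, series) for ttype, series in diffs.items()]
    return pd.DataFrame([r.__dict__ for r in rows])


def fit_trend(transition_type: str, series) -> TrendResult:
    """OLS of a (within - between) series against its 1-based index."""
    y = np.asarray(series, float)
    x = np.arange(1, len(y) + 1, dtype=float)
    if len(y) < 3 or np.ptp(y) == 0:
        return TrendResult(transition_type, 0.0, 0.0, 1.0, len(y))
    fit = stats.linregress(x, y)
    return TrendResult(transition_type, float(fit.slope), float(fit.rvalue ** 2),
                       float(fit.pvalue), len(y))
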