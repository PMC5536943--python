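"""Pseudo-population decoding of trial block identity with an RBF-kernel SVM.

Each run subsamples 200 cells, grid-searches the SVM cost and gamma by
cross-validated accuracy over all available trials, then evaluates 20
train/test resamples: 20 trials drawn per block without replacement, firing
rates normalized per cell by its max over the 120 drawn trials, 10 trials
per block to train and 10 to test.  One evaluation therefore comprises
10 test trials x 6 blocks x 20 resamples = 1200 predictions.

Binary collapses relabel the six blocks before training: modality (auditory
vs visual CS), environment (box 1 vs 2), or relationship (CS-alone vs
CS-US).  Multiclass classification uses one-vs-one voting (the LIBSVM
convention), which shapes the confusion matrices.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.svm import SVC

from ._rng import stage_rng
from .selectivity import window_rates
from .types import AnalysisConfig, SessionSchedule, SpikeTrainSet, TrialTable, ValidationError

__all__ = ["DecodingSpec", "build_feature_matrix", "grid_search", "decode"]

COLLAPSES = ("none", "modality", "environment", "relationship")


def _default_cost_grid() -> tuple[float, ...]:
    return tuple(2.0 ** e for e in range(-5, 16, 2))


def _default_gamma_grid() -> tuple[float, ...]:
    return tuple(2.0 ** e for e in range(-15, 4, 2))


@dataclass(frozen=True)
class DecodingSpec:
    """Decoding protocol parameters (defaults give 1200 tests per run)."""

    n_cells_subsampled: int = 200
    n_runs: int = 20
    n_trials_per_block: int = 20
    n_train_per_block: int = 10
    n_resamples: int = 20
    cost_grid: tuple[float, ...] = field(default_factory=_default_cost_grid)
    gamma_grid: tuple[float, ...] = field(default_factory=_default_gamma_grid)
    cv_folds: int = 5
    period: str = "trial"  # "trial" | "iti"
    collapse: str = "none"
    shuffle_labels: bool = False  # chance-level control

    def __post_init__(self) -> None:
        if self.period not in ("trial", "iti"):
            raise ValidationError("period must be 'trial' or 'iti'")
        if self.collapse not in COLLAPSES:
            raise ValidationError(f"collapse must be one of {COLLAPSES}")
        if self.n_train_per_block >= self.n_trials_per_block:
            raise ValidationError("need test trials: n_train_per_block < n_trials_per_block")

    @property
    def n_test_per_block(self) -> int:
        return self.n_trials_per_block - self.n_train_per_block


def collapse_labels(block_ids: np.ndarray, schedule: SessionSchedule, mode: str) -> np.ndarray:
    """Map block ids to class labels per collapse mode."""
    if mode == "none":
        return np.asarray(block_ids)
    key = {
        "modality": lambda b: b.cs_modality,
        "environment": lambda b: f"box{b.box}",
        "relationship": lambda b: "paired" if b.paired else "alone",
    }[mode]
    lut = {b.block_id: key(b) for b in schedule.blocks}
    return np.array([lut[int(b)] for b in block_ids])


def _rates_matrix(spikes: SpikeTrainSet, trials: TrialTable, schedule: SessionSchedule,
                  config: AnalysisConfig, period: str,
                  rng: np.random.Generator) -> np.ndarray:
    """trials x cells raw rate matrix for one run (ITI bin fixed per run)."""
    cs_on = trials.df["cs_onset_s"].to_numpy(float)
    if period == "trial":
        lo, hi = cs_on, trials.us_equivalent_s(schedule.trial_window_s)
    else:
        w = schedule.trial_window_s
        offs = rng.uniform(0.0, config.iti_window_s - w, size=len(cs_on))
        lo = cs_on - config.iti_window_s + offs
        hi = lo + w
    return np.column_stack([window_rates(u.spike_times_s, lo, hi) for u in spikes])


def _max_normalize(x: np.ndarray) -> np.ndarray:
    """Divide each column (cell) by its max over the rows; all-zero cells dropped."""
    mx = x.max(axis=0)
    keep = mx > 0
    return x[:, keep] / mx[keep]


def build_feature_matrix(spikes: SpikeTrainSet, trials: TrialTable,
                         schedule: SessionSchedule, config: AnalysisConfig,
                         spec: DecodingSpec, rng: np.random.Generator,
                         raw: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Draw ``n_trials_per_block`` trials per block and build (features, labels, rows).

    Features are per-cell max-normalized over the drawn trials only.
    """
    block_ids = trials.df["block_id"].to_numpy()
    if raw is None:
        raw = _rates_matrix(spikes, trials, schedule, config, spec.period, rng)
    if raw.shape[1] < 1:
        raise ValidationError("no cells")
    take = []
    for b in schedule.blocks:
        idx = np.flatnonzero(block_ids == b.block_id)
        if len(idx) < spec.n_trials_per_block:
            raise ValidationError(f"block {b.block_id}: fewer than {spec.n_trials_per_block} trials")
        take.append(rng.choice(idx, size=spec.n_trials_per_block, replace=False))
    rows = np.concatenate(take)
    feats = _max_normalize(raw[rows])
    labels = collapse_labels(block_ids[rows], schedule, spec.collapse)
    return feats, labels, rows


def grid_search(features: np.ndarray, labels: np.ndarray,
                cost_grid, gamma_grid, cv_folds: int = 5,
                rng_seed: int = 0) -> tuple[float, float]:
    """Pick (cost, gamma) maximizing stratified-CV accuracy.

    Ties are broken toward the smallest gamma (smoothest kernel) and then the
    largest cost.  The hyperparameters are selected on all available trials
    but applied to classifiers trained on far fewer, and among equally
    accurate grid points a hard-margin (large cost) solution transfers to the
    smaller training sets, whereas a strongly regularized one can collapse to
    the majority class there.
    """
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValidationError("grid search needs at least two classes")
    cv = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=rng_seed)
    best = (-np.inf, None, None)
    for g in sorted(gamma_grid):
        for c in sorted(cost_grid):
            acc = cross_val_score(SVC(kernel="rbf", C=c, gamma=g),
                                  features, labels, cv=cv).mean()
            if acc > best[0] or (acc == best[0] and g == best[2] and c > best[1]):
                best = (acc, c, g)
    return best[1], best[2]


def decode(spikes: SpikeTrainSet, trials: TrialTable, schedule: SessionSchedule,
           config: AnalysisConfig, spec: DecodingSpec | None = None,
           seed: int = 0) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the full decoding protocol.

    Returns ``(results, confusion)``: per-run accuracy with the chosen
    hyperparameters, and the summed confusion matrix per run in long format.
    Row sums of each confusion matrix equal tested trials per true class;
    accuracy = trace / total.
    """
    spec = spec or DecodingSpec()
    rng = stage_rng(seed, f"decode_{spec.period}_{spec.collapse}")
    n_cells = min(spec.n_cells_subsampled, len(spikes))
    results = []
    conf_rows = []
    block_ids = trials.df["block_id"].to_numpy()
    for run in range(1, spec.n_runs + 1):
        take_cells = rng.choice(len(spikes), size=n_cells, replace=False)
        sub = spikes.subset(sorted(take_cells))
        raw = _rates_matrix(sub, trials, schedule, config, spec.period, rng)
        # hyperparameter selection on all available trials, separately normalized
        all_feats = _max_normalize(raw)
        all_labels = collapse_labels(block_ids, schedule, spec.collapse)
        if spec.shuffle_labels:
            all_labels = rng.permutation(all_labels)
        cost, gamma = grid_search(all_feats, all_labels, spec.cost_grid,
                                  spec.gamma_grid, spec.cv_folds,
                                  rng_seed=int(rng.integers(2 ** 31)))
        classes = np.unique(all_labels)
        conf = np.zeros((len(classes), len(classes)), int)
        cls_index = {c: i for i, c in enumerate(classes)}
        n_correct = 0
        n_total = 0
        for _ in range(spec.n_resamples):
            feats, labels, _rows = build_feature_matrix(
                sub, trials, schedule, config, spec, rng, raw=raw)
            if spec.shuffle_labels:
                labels = rng.permutation(labels)
            # disjoint stratified train/test split within the drawn trials
            train_idx = []
            test_idx = []
            for c in classes:
                idx = np.flatnonzero(labels == c)
                idx = rng.permutation(idx)
                n_tr = len(idx) * spec.n_train_per_block // spec.n_trials_per_block
                train_idx.append(idx[:n_tr])
                test_idx.append(idx[n_tr:])
            train_idx = np.concatenate(train_idx)
            test_idx = np.concatenate(test_idx)
            clf = SVC(kernel="rbf", C=cost, gamma=gamma)
            clf.fit(feats[train_idx], labels[train_idx])
            pred = clf.predict(feats[test_idx])
            truth = labels[test_idx]
            n_correct += int((pred == truth).sum())
            n_total += len(truth)
            for t, p in zip(truth, pred):
                conf[cls_index[t], cls_index[p]] += 1
        results.append({
            "run": run, "period": spec.period, "collapse": spec.collapse,
            "accuracy": n_correct / n_total, "n_tests": n_total,
            "cost": cost, "gamma": gamma, "n_cells": n_cells,
        })
        for i, ct in enumerate(classes):
            for j, cp in enumerate(classes):
                conf_rows.append({"run": run, "period": spec.period,
                                  "collapse": spec.collapse, "true": ct,
                                  "predicted": cp, "count": int(conf[i, j])})
    return pd.DataFrame(results), pd.DataFrame(conf_rows)
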