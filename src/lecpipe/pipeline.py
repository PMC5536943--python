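"""Pipeline orchestration: behavior -> selectivity -> stability -> ensemble -> decoding.

Each stage consumes the in-memory session objects, writes tidy CSV tables to
the output directory, and logs its seed and parameters.  A fixed master seed
makes every stage — and therefore the whole report bundle — reproducible.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from ._rng import stage_rng, stage_seed
from . import behavior, decoding, ensemble, selectivity
from .io import read_session, write_session
from .synth import GeneratorConfig, generate_session
from .types import AnalysisConfig, ValidationError

__all__ = ["run_pipeline", "STAGES"]

STAGES = ("behavior", "selectivity", "stability", "ensemble", "decoding")
log = logging.getLogger("lecpipe")

_FLOAT_FMT = "%.10g"


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)
    log.info("wrote %s (%d rows)", path, len(df))


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name for context."""


def run_pipeline(config: AnalysisConfig, out_dir,
                 session_dir=None, generator: GeneratorConfig | None = None,
                 stages=STAGES, decoding_spec: decoding.DecodingSpec | None = None,
                 run_bin_sweep: bool = False) -> dict[str, Path]:
    """Execute the analysis stages and emit the report bundle.

    Inputs are either a session directory (``session_dir``) or a generator
    configuration (``generator``); exactly one must be given.  Returns the
    paths of the written tables.
    """
    if (session_dir is None) == (generator is None):
        raise ValidationError("provide exactly one of session_dir or generator")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = config.rng_seed
    truth = None
    if generator is not None:
        log.info("generating synthetic session (seed %d)", seed)
        spikes, trials, emg, schedule, truth = generate_session(generator, seed=seed)
    else:
        spikes, trials, emg, schedule = read_session(session_dir)
    paths: dict[str, Path] = {}

    provenance = {
        "seed": seed,
        "stage_seeds": {s: stage_seed(seed, s) for s in STAGES},
        "config": asdict(config),
        "n_units": len(spikes),
        "n_trials": len(trials),
        "stages": list(stages),
        "synthetic": generator is not None,
    }
    (out / "run_info.json").write_text(json.dumps(provenance, indent=1, sort_keys=True))

    cr_labels = None
    for stage in stages:
        log.info("stage: %s", stage)
        try:
            if stage == "behavior":
                if emg is None:
                    log.warning("no EMG trace: skipping behavior stage")
                    continue
                scores = behavior.score_session(emg, trials, schedule)
                cr_labels = scores.labels
                paths["cr_scores"] = out / "cr_scores.csv"
                _write(scores.trial_df, paths["cr_scores"])
                paths["cr_block_stats"] = out / "cr_block_stats.csv"
                _write(scores.block_df, paths["cr_block_stats"])
            elif stage == "selectivity":
                table = selectivity.selectivity_table(spikes, trials, schedule, config, seed=seed)
                paths["selectivity"] = out / "selectivity.csv"
                _write(table, paths["selectivity"])
                for period in ("trial", "iti"):
                    sub = table if period == "iti" else table[table["responsive"]]
                    counts = selectivity.category_counts(sub, period)
                    paths[f"categories_{period}"] = out / f"category_counts_{period}.csv"
                    _write(counts, paths[f"categories_{period}"])
                if cr_labels is not None:
                    cr_tab = selectivity.cr_correlation_table(
                        spikes, trials, cr_labels, schedule, config, seed=seed)
                    paths["cr_correlation"] = out / "cr_correlation.csv"
                    _write(cr_tab, paths["cr_correlation"])
            elif stage == "stability":
                stab = selectivity.stability_table(spikes, trials, schedule, config)
                paths["stability"] = out / "stability.csv"
                _write(stab, paths["stability"])
                if run_bin_sweep:
                    sweep = selectivity.bin_size_sweep(spikes, trials, schedule, config, seed=seed)
                    paths["bin_sweep"] = out / "bin_size_sweep.csv"
                    _write(sweep, paths["bin_sweep"])
            elif stage == "ensemble":
                frames = []
                for period in ("trial", "iti"):
                    bp = ensemble.block_pair_comparison(
                        spikes, trials, schedule, config, period=period, seed=seed)
                    bp.insert(0, "period", period)
                    frames.append(bp)
                paths["blockpair"] = out / "ensemble_blockpair.csv"
                _write(pd.concat(frames, ignore_index=True), paths["blockpair"])
                m = ensemble.iti_correlation_matrix(
                    spikes, trials, schedule, config, stage_rng(seed, "iti_matrix"))
                paths["iti_matrix"] = out / "iti_matrix.csv"
                np.savetxt(paths["iti_matrix"], m, delimiter=",", fmt="%.6g")
                sim = ensemble.similarity_scores(spikes, trials, schedule, config, seed=seed)
                paths["similarity"] = out / "similarity_scores.csv"
                _write(sim, paths["similarity"])
                try:
                    trend = ensemble.session_sliding_trend(spikes, trials, schedule, config, seed=seed)
                    paths["trend"] = out / "trend.csv"
                    _write(trend, paths["trend"])
                except ValidationError as exc:
                    log.warning("sliding trend skipped: %s", exc)
            elif stage == "decoding":
                spec = decoding_spec or decoding.DecodingSpec()
                res_frames, conf_frames = [], []
                for period in ("trial", "iti"):
                    from dataclasses import replace
                    res, conf = decoding.decode(
                        spikes, trials, schedule, config,
                        replace(spec, period=period), seed=seed)
                    res_frames.append(res)
                    conf_frames.append(conf)
                paths["decoding"] = out / "decoding_results.csv"
                _write(pd.concat(res_frames, ignore_index=True), paths["decoding"])
                paths["confusion"] = out / "confusion_matrices.csv"
                _write(pd.concat(conf_frames, ignore_index=True), paths["confusion"])
            else:
                raise ValidationError(f"unknown stage {stage!r}")
        except Exception as exc:
            raise StageError(f"stage '{stage}' failed: {exc}") from exc

    if truth is not None and truth["cells"] is not None:
        truth_df = pd.DataFrame([
            {"unit_id": c.unit_id, "category_label": c.category_label,
             "responsive": c.responsive, "layer": c.layer,
             "session_order": c.session_order}
            for c in truth["cells"]])
        paths["ground_truth"] = out / "ground_truth_cells.csv"
        _write(truth_df, paths["ground_truth"])
    return paths
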