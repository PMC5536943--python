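"""Readers and writers for the plain-text session format.

A session directory holds:

* ``spikes.csv`` — ``unit_id,rat_id,session_id,layer,spike_time_s``
* ``trials.csv`` — ``trial_index,block_id,cs_onset_s,cs_offset_s,us_onset_s``
  (``us_onset_s`` blank on CS-alone trials)
* ``schedule.json`` — block specs plus ITI bounds and stimulus durations
* ``emg.csv`` (``t_s,amplitude``) or ``emg.f32`` raw little-endian float32
  with an ``emg.json`` sidecar carrying ``rate_hz``/``t0_s``

Downstream stages consume only the in-memory objects; nothing re-reads raw
files after :func:`read_session`.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .types import (
    BlockSpec,
    EMGTrace,
    SessionSchedule,
    SpikeTrainSet,
    TrialTable,
    Unit,
    ValidationError,
)

__all__ = ["read_session", "write_session", "schedule_to_dict", "schedule_from_dict"]

# pandas default float formatting writes the shortest exact repr, so numeric
# columns round-trip bit-identically


def schedule_to_dict(schedule: SessionSchedule) -> dict:
    return {
        "blocks": [
            {
                "block_id": b.block_id,
                "cs_modality": b.cs_modality,
                "box": b.box,
                "paired": b.paired,
                "n_trials": b.n_trials,
            }
            for b in schedule.blocks
        ],
        "iti_min_s": schedule.iti_min_s,
        "iti_max_s": schedule.iti_max_s,
        "cs_duration_s": schedule.cs_duration_s,
        "trace_interval_s": schedule.trace_interval_s,
        "us_duration_s": schedule.us_duration_s,
        "emg_rate_hz": schedule.emg_rate_hz,
    }


def schedule_from_dict(d: dict) -> SessionSchedule:
    try:
        blocks = [BlockSpec(**b) for b in d["blocks"]]
        kwargs = {k: d[k] for k in (
            "iti_min_s", "iti_max_s", "cs_duration_s", "trace_interval_s",
            "us_duration_s", "emg_rate_hz") if k in d}
    except (KeyError, TypeError) as exc:
        raise ValidationError(f"malformed schedule descriptor: {exc}") from exc
    return SessionSchedule(blocks=tuple(blocks), **kwargs)


def write_session(out_dir, spikes: SpikeTrainSet, trials: TrialTable,
                  emg: EMGTrace | None, schedule: SessionSchedule,
                  emg_format: str = "f32") -> dict[str, Path]:
    """Write a session to ``out_dir``; returns the paths written.

    Output is bit-stable for identical inputs. ``emg_format`` is ``"f32"``
    (raw float32 + JSON sidecar, compact) or ``"csv"``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    rows = []
    for u in spikes:
        for t in u.spike_times_s:
            rows.append((u.unit_id, u.rat_id, u.session_id, u.layer, t))
    spike_df = pd.DataFrame(rows, columns=["unit_id", "rat_id", "session_id", "layer", "spike_time_s"])
    # header-only file when there are no spikes at all
    paths["spikes"] = out / "spikes.csv"
    spike_df.to_csv(paths["spikes"], index=False)
    # units with zero spikes still need a row in the roster
    roster = pd.DataFrame(
        [(u.unit_id, u.rat_id, u.session_id, u.layer) for u in spikes],
        columns=["unit_id", "rat_id", "session_id", "layer"],
    )
    paths["units"] = out / "units.csv"
    roster.to_csv(paths["units"], index=False)

    paths["trials"] = out / "trials.csv"
    trials.df[TrialTable.REQUIRED].to_csv(paths["trials"], index=False)

    paths["schedule"] = out / "schedule.json"
    paths["schedule"].write_text(json.dumps(schedule_to_dict(schedule), indent=1, sort_keys=True))

    if emg is not None:
        if not np.all(np.isfinite(emg.samples)):
            raise ValidationError("refusing to write non-finite EMG samples")
        if emg_format == "csv":
            paths["emg"] = out / "emg.csv"
            t = emg.t0_s + np.arange(len(emg.samples)) / emg.rate_hz
            pd.DataFrame({"t_s": t, "amplitude": emg.samples}).to_csv(
                paths["emg"], index=False)
        elif emg_format == "f32":
            paths["emg"] = out / "emg.f32"
            emg.samples.astype("<f4").tofile(paths["emg"])
        else:
            raise ValueError(f"unknown emg_format {emg_format!r}")
        sidecar = out / "emg.json"
        sidecar.write_text(json.dumps(
            {"rate_hz": emg.rate_hz, "t0_s": emg.t0_s, "format": emg_format},
            indent=1, sort_keys=True))
        paths["emg_sidecar"] = sidecar
    return paths


def _read_emg(session_dir: Path) -> EMGTrace | None:
    sidecar = session_dir / "emg.json"
    if not sidecar.exists():
        return None
    meta = json.loads(sidecar.read_text())
    if meta.get("format", "f32") == "csv":
        df = pd.read_csv(session_dir / "emg.csv")
        if "amplitude" not in df.columns:
            raise ValidationError("emg.csv must have an 'amplitude' column")
        samples = df["amplitude"].to_numpy(float)
    else:
        samples = np.fromfile(session_dir / "emg.f32", dtype="<f4").astype(float)
    return EMGTrace(rate_hz=float(meta["rate_hz"]), samples=samples, t0_s=float(meta.get("t0_s", 0.0)))


def read_session(session_dir) -> tuple[SpikeTrainSet, TrialTable, EMGTrace | None, SessionSchedule]:
    """Read and cross-validate a session directory written by :func:`write_session`.

    Raises :class:`ValidationError` on missing columns, unsorted spike times,
    or trial events outside the recorded span.
    """
    session_dir = Path(session_dir)
    schedule = schedule_from_dict(json.loads((session_dir / "schedule.json").read_text()))

    trial_df = pd.read_csv(session_dir / "trials.csv")
    trials = TrialTable(trial_df, schedule=schedule)

    spike_df = pd.read_csv(session_dir / "spikes.csv")
    need = {"unit_id", "rat_id", "session_id", "layer", "spike_time_s"}
    if not need.issubset(spike_df.columns):
        raise ValidationError(f"spikes.csv missing columns {sorted(need - set(spike_df.columns))}")
    roster_path = session_dir / "units.csv"
    if roster_path.exists():
        roster = pd.read_csv(roster_path)
    else:
        roster = spike_df[["unit_id", "rat_id", "session_id", "layer"]].drop_duplicates()
    units = []
    grouped = {k: v for k, v in spike_df.groupby("unit_id", sort=False)}
    for row in roster.itertuples(index=False):
        sub = grouped.get(row.unit_id)
        t = np.sort(sub["spike_time_s"].to_numpy(float)) if sub is not None else np.array([])
        if sub is not None and not np.array_equal(t, sub["spike_time_s"].to_numpy(float)):
            raise ValidationError(f"unit {row.unit_id}: spike times not sorted in file")
        units.append(Unit(str(row.unit_id), t, str(row.rat_id), str(row.session_id), str(row.layer)))
    spikes = SpikeTrainSet(units)

    emg = _read_emg(session_dir)
    if emg is not None and len(trials):
        if trials.end_s > emg.t0_s + emg.duration_s + 1e-6:
            raise ValidationError("trial events extend beyond the EMG recording span")
    for u in spikes:
        if len(u.spike_times_s) and len(trials) and u.spike_times_s[-1] < 0:
            raise ValidationError("negative spike times")
    return spikes, trials, emg, schedule
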