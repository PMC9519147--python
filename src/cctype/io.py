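"""On-disk dialects: BIDS-style events TSV, flat-binary continuous data with
a JSON sidecar, and spike-time TSV with JSON metadata.

Write -> read round-trips reproduce values exactly: event and spike times to
1 ns (written with 9 decimals), voltages bit-exact (little-endian float32,
channel-major).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .core import ContinuousRecording, SpikeTrain, TrialTable


class ParseError(ValueError):
    """A file does not conform to its documented dialect."""


# ---------------------------------------------------------------- events TSV

_EVENT_COLS = ["onset", "duration", "trial_type", "trial_id", "run_id", "task_onset", "task_offset"]


def write_events(table: TrialTable, path) -> None:
    df = table.df
    out = pd.DataFrame(
        {
            "onset": df["cue_onset"],
            "duration": df["task_offset"] - df["cue_onset"],
            "trial_type": df["condition"],
            "trial_id": df["trial_id"],
            "run_id": df["run_id"],
            "task_onset": df["task_onset"],
            "task_offset": df["task_offset"],
        }
    )
    out.to_csv(path, sep="\t", index=False, float_format="%.9f")


def read_events(path) -> TrialTable:
    try:
        df = pd.read_csv(path, sep="\t")
    except Exception as e:  # noqa: BLE001
        raise ParseError(f"{path}: cannot parse events TSV: {e}") from e
    missing = [c for c in _EVENT_COLS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    for col in ("onset", "duration", "task_onset", "task_offset"):
        if df[col].isna().any():
            raise ParseError(f"{path}: NaN in column {col!r}")
    if not df["onset"].is_monotonic_increasing:
        raise ParseError(f"{path}: onsets not monotonically increasing")
    trials = pd.DataFrame(
        {
            "trial_id": df["trial_id"].astype(int),
            "run_id": df["run_id"].astype(int),
            "condition": df["trial_type"],
            "cue_onset": df["onset"].astype(float),
            "task_onset": df["task_onset"].astype(float),
            "task_offset": df["task_offset"].astype(float),
        }
    )
    try:
        return TrialTable(trials)
    except ValueError as e:
        raise ParseError(f"{path}: {e}") from e


# -------------------------------------------------- continuous binary + JSON

def write_continuous(rec: ContinuousRecording, path) -> None:
    """Write ``<path>.bin`` (little-endian float32, channel-major) + ``<path>.json``."""
    path = Path(path)
    data = np.ascontiguousarray(rec.data, dtype="<f4")
    data.tofile(path.with_suffix(".bin"))
    sidecar = {
        "fs": rec.fs,
        "t0": rec.t0,
        "n_channels": int(data.shape[0]),
        "n_samples": int(data.shape[1]),
        "channel_ids": [str(c) for c in rec.channel_ids],
        "probe_of_channel": {str(k): str(v) for k, v in rec.probe_of_channel.items()},
        "dtype": "<f4",
        "order": "channel-major",
        "units": "uV",
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def read_continuous(path) -> ContinuousRecording:
    path = Path(path)
    try:
        meta = json.loads(path.with_suffix(".json").read_text())
    except Exception as e:  # noqa: BLE001
        raise ParseError(f"{path}: cannot read sidecar: {e}") from e
    for key in ("fs", "n_channels", "n_samples", "channel_ids", "dtype"):
        if key not in meta:
            raise ParseError(f"{path}: sidecar missing field {key!r}")
    data = np.fromfile(path.with_suffix(".bin"), dtype=meta["dtype"])
    n_ch, n_s = meta["n_channels"], meta["n_samples"]
    if data.size != n_ch * n_s:
        raise ParseError(f"{path}: binary size {data.size} != {n_ch}x{n_s}")
    data = data.reshape(n_ch, n_s)
    if np.isnan(data).any():
        raise ParseError(f"{path}: NaN samples in binary payload")
    return ContinuousRecording(
        data, float(meta["fs"]), list(meta["channel_ids"]), dict(meta.get("probe_of_channel", {})), float(meta.get("t0", 0.0))
    )


# ------------------------------------------------------------- spike trains

def write_spikes(trains: Sequence[SpikeTrain], path) -> None:
    """Write ``<path>.tsv`` (unit_id, spike_time_s) + ``<path>.json`` metadata."""
    path = Path(path)
    with open(path.with_suffix(".tsv"), "w") as fh:
        fh.write("unit_id\tspike_time_s\n")
        for u in trains:
            for t in u.spike_times:
                fh.write(f"{u.unit_id}\t{t:.9f}\n")
    meta = {
        str(u.unit_id): {"probe_id": None if u.probe_id is None else str(u.probe_id),
                          "isolation": u.isolation, "n_spikes": int(u.n_spikes)}
        for u in trains
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1))


def read_spikes(path) -> list[SpikeTrain]:
    path = Path(path)
    tsv = path.with_suffix(".tsv")
    with open(tsv) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    if header[:2] != ["unit_id", "spike_time_s"]:
        raise ParseError(f"{tsv}: malformed header {header}")
    df = pd.read_csv(tsv, sep="\t")
    meta = {}
    if path.with_suffix(".json").exists():
        meta = json.loads(path.with_suffix(".json").read_text())
    trains = []
    unit_order = list(dict.fromkeys(df["unit_id"])) if len(df) else []
    for uid in set(meta) - {str(u) for u in unit_order}:
        unit_order.append(uid)  # units with zero spikes survive via metadata
    for uid in unit_order:
        times = df.loc[df["unit_id"].astype(str) == str(uid), "spike_time_s"].to_numpy(float)
        if np.isnan(times).any():
            raise ParseError(f"{tsv}: NaN spike time for unit {uid}")
        m = meta.get(str(uid), {})
        trains.append(
            SpikeTrain(uid, np.sort(times), probe_id=m.get("probe_id"), isolation=m.get("isolation", "unknown"))
        )
    return trains
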