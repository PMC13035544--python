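"""Tabular readers/writers for sample streams, event tables and configs.

Samples file: delimited text (CSV or TSV, autodetected by extension) with
columns ``trial_id, t_ms, pupil`` and optionally ``gaze_x, gaze_y, valid``,
rows grouped by trial. Events file: ``trial_id, onset_ms, offset_ms`` and
optionally ``is_return``, with times on the trace's clock.
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .types import DataError, FormatError, PupilTrace, SaccadeEvent, check_saccades

REQUIRED_SAMPLE_COLS = ("trial_id", "t_ms", "pupil")
REQUIRED_EVENT_COLS = ("trial_id", "onset_ms", "offset_ms")


def _read_table(path) -> pd.DataFrame:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    return pd.read_csv(path, sep=sep)


def _require(df: pd.DataFrame, cols, path) -> None:
    for c in cols:
        if c not in df.columns:
            raise FormatError(f"{path}: missing required column {c!r}")


def read_samples(path, fs: float) -> list[PupilTrace]:
    """Read a samples file into one :class:`PupilTrace` per trial.

    Timestamps are normalized to start at 0 per trial; rows with non-finite
    pupil size are marked invalid (the value is kept as NaN). Non-uniform
    sampling beyond tolerance raises :class:`DataError`.
    """
    df = _read_table(path)
    _require(df, REQUIRED_SAMPLE_COLS, path)
    traces = []
    for trial_id, g in df.groupby("trial_id", sort=False):
        t = g["t_ms"].to_numpy(dtype=float)
        t = t - t[0]
        pupil = g["pupil"].to_numpy(dtype=float)
        if "valid" in g.columns:
            valid = g["valid"].to_numpy().astype(bool)
        else:
            valid = np.ones(len(g), dtype=bool)
        valid &= np.isfinite(pupil)
        kw = {}
        for col in ("gaze_x", "gaze_y"):
            if col in g.columns:
                kw[col] = g[col].to_numpy(dtype=float)
        traces.append(
            PupilTrace(trial_id=trial_id, t=t, fs=fs, pupil=pupil, valid=valid, **kw)
        )
    return traces


def write_samples(traces: list[PupilTrace], path) -> None:
    """Write traces back to a CSV samples file (inverse of read_samples)."""
    frames = []
    for tr in traces:
        d = {"trial_id": tr.trial_id, "t_ms": tr.t, "pupil": tr.pupil,
             "valid": tr.valid.astype(int)}
        if tr.gaze_x is not None:
            d["gaze_x"] = tr.gaze_x
        if tr.gaze_y is not None:
            d["gaze_y"] = tr.gaze_y
        frames.append(pd.DataFrame(d))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def ms_to_index(t_ms: float, trace: PupilTrace) -> int:
    """Map a time on the trace clock to a sample index by round-half-up."""
    frac = (t_ms - float(trace.t[0])) / trace.dt_ms
    return int(math.floor(frac + 0.5))


def read_events(path, traces: list[PupilTrace]) -> dict[object, list[SaccadeEvent]]:
    """Read a saccade-event table keyed by trial id.

    Onset/offset times are mapped to sample indices by round-half-up on the
    trace clock; events are sorted and overlap-checked per trial. An event
    outside its trace's time range, or overlapping another, raises
    :class:`DataError`.
    """
    df = _read_table(path)
    _require(df, REQUIRED_EVENT_COLS, path)
    by_id = {tr.trial_id: tr for tr in traces}
    out: dict[object, list[SaccadeEvent]] = {tr.trial_id: [] for tr in traces}
    for _, row in df.iterrows():
        tid = row["trial_id"]
        if tid not in by_id:
            raise DataError(f"{path}: event for unknown trial {tid!r}")
        tr = by_id[tid]
        onset = ms_to_index(float(row["onset_ms"]), tr)
        offset = ms_to_index(float(row["offset_ms"]), tr)
        if onset < 0 or offset >= len(tr):
            raise DataError(
                f"{path}: event [{row['onset_ms']}, {row['offset_ms']}] ms "
                f"outside trace for trial {tid!r}"
            )
        is_return = None
        if "is_return" in df.columns and not pd.isna(row["is_return"]):
            is_return = bool(row["is_return"])
        out[tid].append(SaccadeEvent(onset=onset, offset=offset, is_return=is_return))
    for tid, events in out.items():
        events.sort(key=lambda s: s.onset)
        check_saccades(events, by_id[tid])
    return out


def write_events(events: Mapping[object, list[SaccadeEvent]],
                 traces: list[PupilTrace], path) -> None:
    by_id = {tr.trial_id: tr for tr in traces}
    rows = []
    for tid, evs in events.items():
        tr = by_id[tid]
        for s in evs:
            rows.append({
                "trial_id": tid,
                "onset_ms": float(tr.t[s.onset]),
                "offset_ms": float(tr.t[s.offset]),
                "is_return": "" if s.is_return is None else int(s.is_return),
            })
    pd.DataFrame(rows).to_csv(path, index=False)


def load_config(path) -> dict:
    """Load a flat key-value config file (YAML or JSON by extension)."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        cfg = json.loads(text)
    else:
        cfg = yaml.safe_load(text)
    if not isinstance(cfg, dict):
        raise FormatError(f"{path}: config must be a flat mapping")
    return cfg
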