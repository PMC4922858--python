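"""CSV / JSON interchange for events, traces and reports.

Events travel as tidy CSV with columns
``molecule_id, channel, t_bind_s, t_release_s, censored`` (0/1);
traces as tidy CSV with columns
``molecule_id, channel, frame_index, t_mid_s, intensity`` plus a YAML
sidecar (``<stem>.meta.yaml``) holding the acquisition metadata.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from .detect import EventInterval
from .simulate import AcquisitionConfig, IntensityTrace, MoleculeTruth

__all__ = [
    "events_to_frame", "frame_to_events",
    "truths_to_events", "truths_to_frame",
    "write_events_csv", "read_events_csv",
    "traces_to_frame", "write_traces_csv", "read_traces_csv",
    "write_json",
]

EVENT_COLUMNS = ["molecule_id", "channel", "t_bind_s", "t_release_s",
                 "censored"]
TRACE_COLUMNS = ["molecule_id", "channel", "frame_index", "t_mid_s",
                 "intensity"]


def truths_to_events(truths: Iterable[MoleculeTruth]) -> list[EventInterval]:
    """Flatten ground-truth schedules to per-channel event intervals."""
    out = []
    for truth in truths:
        for channel, ivs in truth.intervals.items():
            for t0, t1, censored in ivs:
                if t1 > t0:
                    out.append(EventInterval(truth.molecule_id, channel,
                                             t0, t1, censored))
    return out


def events_to_frame(events: Sequence[EventInterval]) -> pd.DataFrame:
    rows = [(ev.molecule_id, ev.channel, ev.t_start, ev.t_end,
             int(ev.censored)) for ev in events]
    return pd.DataFrame(rows, columns=EVENT_COLUMNS)


def truths_to_frame(truths: Iterable[MoleculeTruth]) -> pd.DataFrame:
    return events_to_frame(truths_to_events(truths))


def frame_to_events(df: pd.DataFrame) -> list[EventInterval]:
    return [EventInterval(int(r.molecule_id), str(r.channel),
                          float(r.t_bind_s), float(r.t_release_s),
                          bool(r.censored))
            for r in df.itertuples(index=False)]


def write_events_csv(events: Sequence[EventInterval], path) -> Path:
    path = Path(path)
    events_to_frame(events).to_csv(path, index=False)
    return path


def read_events_csv(path) -> list[EventInterval]:
    return frame_to_events(pd.read_csv(path))


def traces_to_frame(traces: Sequence[IntensityTrace]) -> pd.DataFrame:
    frames = []
    for tr in traces:
        frames.append(pd.DataFrame({
            "molecule_id": tr.molecule_id,
            "channel": tr.channel,
            "frame_index": np.arange(len(tr)),
            "t_mid_s": tr.t_mid,
            "intensity": tr.intensity,
        }))
    if not frames:
        return pd.DataFrame(columns=TRACE_COLUMNS)
    return pd.concat(frames, ignore_index=True)


def write_traces_csv(traces: Sequence[IntensityTrace], path,
                     config: AcquisitionConfig | None = None) -> Path:
    path = Path(path)
    traces_to_frame(traces).to_csv(path, index=False)
    if config is not None:
        meta = asdict(config)
        meta["labels_per_channel"] = dict(meta["labels_per_channel"])
        sidecar = path.with_name(path.stem + ".meta.yaml")
        sidecar.write_text(yaml.safe_dump(meta, sort_keys=True))
    return path


def read_traces_csv(path) -> list[IntensityTrace]:
    path = Path(path)
    df = pd.read_csv(path)
    sidecar = path.with_name(path.stem + ".meta.yaml")
    if sidecar.exists():
        meta = yaml.safe_load(sidecar.read_text())
        spacing = float(meta["frame_spacing"])
        duration = float(meta["frame_duration"])
    else:
        spacing = duration = None
    traces = []
    for (mol, chan), grp in df.groupby(["molecule_id", "channel"],
                                       sort=True):
        grp = grp.sort_values("frame_index")
        t = grp["t_mid_s"].to_numpy(dtype=float)
        sp = spacing if spacing is not None else float(np.median(np.diff(t)))
        du = duration if duration is not None else sp
        traces.append(IntensityTrace(int(mol), str(chan), t,
                                     grp["intensity"].to_numpy(dtype=float),
                                     sp, du))
    return traces


def write_json(obj, path) -> Path:
    path = Path(path)

    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON-serializable: {type(o)}")

    path.write_text(json.dumps(obj, indent=2, default=_default))
    return path
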