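"""Plain-text readers and writers: traces/geometry/spikes CSV, epochs JSON,
configs YAML. Everything round-trips so the pipeline stages compose on disk
as well as in memory.
"""
from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .datatypes import CellGeometry, Epoch, RecordingSession, SpikeTrain
from .synthetic import SynthConfig

__all__ = [
    "write_traces_csv", "read_traces_csv",
    "write_geometry_csv", "read_geometry_csv",
    "write_epochs_json", "read_epochs_json",
    "write_spikes_csv", "read_spikes_csv",
    "write_session", "read_session",
    "write_config_yaml", "read_config_yaml",
    "write_json",
]


def write_traces_csv(session: RecordingSession, path) -> None:
    """Frames x cells intensity table; header row holds the cell ids."""
    session.traces.to_csv(path, index=False, float_format="%.4f")


def read_traces_csv(path, frame_interval: float) -> pd.DataFrame:
    df = pd.read_csv(path)
    df.attrs["frame_interval"] = frame_interval
    return df


def write_geometry_csv(geometry: dict[str, CellGeometry], path) -> None:
    rows = [{"cell_id": g.cell_id, "slice_id": g.slice_id,
             "x_min": g.x_min, "y_min": g.y_min, "x_max": g.x_max, "y_max": g.y_max,
             "pixel_size": g.pixel_size} for g in geometry.values()]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_geometry_csv(path) -> dict[str, CellGeometry]:
    df = pd.read_csv(path)
    return {r.cell_id: CellGeometry(r.cell_id, r.x_min, r.y_min, r.x_max, r.y_max,
                                    r.pixel_size, getattr(r, "slice_id", "slice0"))
            for r in df.itertuples()}


def write_epochs_json(epochs: list[Epoch], path) -> None:
    payload = [{"name": e.name, "start_frame": e.start, "end_frame": e.end,
                "solution": e.solution} for e in epochs]
    Path(path).write_text(json.dumps(payload, indent=2))


def read_epochs_json(path) -> list[Epoch]:
    payload = json.loads(Path(path).read_text())
    return [Epoch(e["name"], e["start_frame"], e["end_frame"], e.get("solution", "control"))
            for e in payload]


def write_spikes_csv(trains: dict[str, SpikeTrain], path) -> None:
    """Long format: one row per spike (cell_id, spike_frame) plus grid info."""
    rows = [{"cell_id": cid, "spike_frame": int(f), "n_frames": t.n_frames,
             "frame_interval": t.frame_interval}
            for cid, t in trains.items() for f in t.spike_frames]
    # silent cells still need a grid record
    empty = [{"cell_id": cid, "spike_frame": -1, "n_frames": t.n_frames,
              "frame_interval": t.frame_interval}
             for cid, t in trains.items() if t.n_spikes == 0]
    pd.DataFrame(rows + empty).to_csv(path, index=False)


def read_spikes_csv(path) -> dict[str, SpikeTrain]:
    df = pd.read_csv(path)
    trains: dict[str, SpikeTrain] = {}
    for cid, g in df.groupby("cell_id", sort=False):
        frames = np.sort(g.loc[g.spike_frame >= 0, "spike_frame"].to_numpy(dtype=np.int64))
        trains[str(cid)] = SpikeTrain(str(cid), frames, int(g.n_frames.iloc[0]),
                                      float(g.frame_interval.iloc[0]))
    return trains


def write_session(session: RecordingSession, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_traces_csv(session, out / "traces.csv")
    write_geometry_csv(session.geometry, out / "geometry.csv")
    write_epochs_json(session.epochs, out / "epochs.json")
    meta = dict(session.metadata, pixel_size=session.pixel_size,
                frame_interval=session.frame_interval)
    (out / "session.json").write_text(json.dumps(meta, indent=2, default=str))


def read_session(in_dir) -> RecordingSession:
    p = Path(in_dir)
    meta = json.loads((p / "session.json").read_text())
    frame_interval = float(meta.pop("frame_interval"))
    pixel_size = float(meta.pop("pixel_size"))
    return RecordingSession(
        traces=pd.read_csv(p / "traces.csv"),
        geometry=read_geometry_csv(p / "geometry.csv"),
        epochs=read_epochs_json(p / "epochs.json"),
        pixel_size=pixel_size,
        frame_interval=frame_interval,
        metadata=meta,
    )


def write_config_yaml(config: SynthConfig, path) -> None:
    d = dataclasses.asdict(config)
    if isinstance(d.get("cells_per_slice"), tuple):
        d["cells_per_slice"] = list(d["cells_per_slice"])
    if d.get("epochs") is not None:
        d["epochs"] = [list(e) for e in d["epochs"]]
    Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


def read_config_yaml(path) -> SynthConfig:
    d = yaml.safe_load(Path(path).read_text())
    if d.get("epochs") is not None:
        d["epochs"] = tuple(tuple(e) for e in d["epochs"])
    return SynthConfig(**d)


def write_json(obj, path) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if dataclasses.is_dataclass(o):
            return dataclasses.asdict(o)
        if isinstance(o, (set, frozenset)):
            return sorted(o)
        raise TypeError(f"not JSON serializable: {type(o)}")
    Path(path).write_text(json.dumps(obj, indent=2, default=default))
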