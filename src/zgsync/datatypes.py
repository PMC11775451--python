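"""Core data containers shared across the analysis pipeline.

All frame indices are 0-based and epochs are half-open ``[start, end)``.
Times are seconds, distances are micrometres unless a field says otherwise.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "FluorescenceTrace",
    "SpikeTrain",
    "CellGeometry",
    "Epoch",
    "RecordingSession",
    "FrapTrace",
]


@dataclass(frozen=True)
class FluorescenceTrace:
    """Raw per-cell fluorescence intensity over time (arbitrary units)."""

    cell_id: str
    intensities: np.ndarray
    frame_interval: float

    def __post_init__(self) -> None:
        arr = np.asarray(self.intensities, dtype=float)
        object.__setattr__(self, "intensities", arr)
        if arr.ndim != 1 or arr.size < 2:
            raise ValueError(f"trace {self.cell_id!r} must be a 1-D series of length >= 2")
        if not np.all(np.isfinite(arr)):
            raise ValueError(f"trace {self.cell_id!r} contains non-finite values")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")

    @property
    def n_frames(self) -> int:
        return int(self.intensities.size)


@dataclass(frozen=True)
class SpikeTrain:
    """Per-cell spike events as strictly increasing frame indices on a fixed grid."""

    cell_id: str
    spike_frames: np.ndarray
    n_frames: int
    frame_interval: float

    def __post_init__(self) -> None:
        frames = np.asarray(self.spike_frames, dtype=np.int64).ravel()
        object.__setattr__(self, "spike_frames", frames)
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        if frames.size:
            if frames.min() < 0 or frames.max() >= self.n_frames:
                raise ValueError(f"spike frames of {self.cell_id!r} outside [0, n_frames)")
            if np.any(np.diff(frames) <= 0):
                raise ValueError(f"spike frames of {self.cell_id!r} must be strictly increasing")

    @property
    def n_spikes(self) -> int:
        return int(self.spike_frames.size)

    @property
    def duration(self) -> float:
        """Total recording span covered by the train, in seconds."""
        return self.n_frames * self.frame_interval

    @property
    def rate(self) -> float:
        """Mean firing rate in spikes/s over the full grid."""
        return self.n_spikes / self.duration


@dataclass(frozen=True)
class CellGeometry:
    """Axis-aligned bounding rectangle of one cell ROI, in pixel units.

    The rectangle spans ``[x_min, x_max] x [y_min, y_max]`` inclusive; its
    midpoint is the cell centre used for distance calculations.
    """

    cell_id: str
    x_min: float
    y_min: float
    x_max: float
    y_max: float
    pixel_size: float
    slice_id: str = "slice0"

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive (um/pixel)")
        if self.x_max < self.x_min or self.y_max < self.y_min:
            raise ValueError("rectangle extents are inverted")

    @property
    def center(self) -> tuple[float, float]:
        return ((self.x_min + self.x_max) / 2.0, (self.y_min + self.y_max) / 2.0)

    @property
    def center_um(self) -> tuple[float, float]:
        cx, cy = self.center
        return (cx * self.pixel_size, cy * self.pixel_size)


@dataclass(frozen=True)
class Epoch:
    """A contiguous recording interval under one perfusion condition.

    ``solution`` labels the perfusate; the synthetic generator treats
    ``solution == "cbx"`` as the gap-junction-blocker epoch.
    """

    name: str
    start: int
    end: int
    solution: str = "control"

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise ValueError(f"epoch {self.name!r}: require 0 <= start < end")

    @property
    def n_frames(self) -> int:
        return self.end - self.start

    def duration(self, frame_interval: float) -> float:
        return self.n_frames * frame_interval


@dataclass
class RecordingSession:
    """A cohort of traces plus geometry, epochs and metadata.

    ``traces`` is a frames x cells DataFrame whose columns are cell ids;
    ``geometry`` maps cell id -> :class:`CellGeometry`. Cells from several
    slices may share one session; pairwise statistics are only ever formed
    within a slice.
    """

    traces: pd.DataFrame
    geometry: dict[str, CellGeometry]
    epochs: list[Epoch]
    pixel_size: float
    frame_interval: float
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.traces.shape[0] < 2:
            raise ValueError("session needs at least 2 frames")
        missing = set(self.traces.columns) - set(self.geometry)
        if self.geometry and missing:
            raise ValueError(f"geometry missing for cells: {sorted(missing)[:5]} ...")
        n = self.n_frames
        spans = sorted((e.start, e.end) for e in self.epochs)
        for (s0, e0), (s1, _) in zip(spans, spans[1:]):
            if s1 < e0:
                raise ValueError("epochs overlap")
        if self.epochs and (spans[0][0] < 0 or spans[-1][1] > n):
            raise ValueError("epochs extend beyond recording")

    @property
    def cell_ids(self) -> list[str]:
        return list(self.traces.columns)

    @property
    def n_frames(self) -> int:
        return int(self.traces.shape[0])

    @property
    def slice_of(self) -> dict[str, str]:
        return {cid: g.slice_id for cid, g in self.geometry.items()}

    def trace(self, cell_id: str) -> FluorescenceTrace:
        return FluorescenceTrace(cell_id, self.traces[cell_id].to_numpy(), self.frame_interval)

    def epoch(self, name: str) -> Epoch:
        for e in self.epochs:
            if e.name == name:
                return e
        raise KeyError(f"no epoch named {name!r}")


@dataclass
class FrapTrace:
    """A photobleaching recovery time course.

    ``bleach_index`` is the first sample after the bleach pulse. ``pre_window``
    and ``post_window`` (seconds) are the averaging spans used for the
    pre-bleach reference and the end-of-trace plateau.
    """

    times: np.ndarray
    intensities: np.ndarray
    bleach_index: int
    pre_window: float = 5.0
    post_window: float = 10.0
    label: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        f = np.asarray(self.intensities, dtype=float)
        self.times, self.intensities = t, f
        if t.shape != f.shape or t.ndim != 1:
            raise ValueError("times and intensities must be matching 1-D arrays")
        if not (0 < self.bleach_index < t.size - 1):
            raise ValueError("bleach_index must be interior to the trace")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.pre_window <= 0 or self.post_window <= 0:
            raise ValueError("averaging windows must be positive")
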