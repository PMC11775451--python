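"""Synthetic recordings of bursting, partially synchronized rosette cells.

The generator emulates calcium imaging of acute adrenal slices: zona
glomerulosa cells sit in rosettes (glomeruli) of a few cells, fire ~1 Hz
calcium spikes clustered into bursts, and a minority of near-neighbour
pairs within a rosette share a large fraction of their spikes. Epochs can
carry a gap-junction-blocker condition that suppresses both firing rate and
pairwise synchrony. Everything downstream (detection, Jaccard synchrony,
perturbation and FRAP analysis) is validated against the ground truth this
module returns.

Model
-----
Each cell's spike train is a burst-renewal process: bursts start after
exponentially distributed quiescent gaps, contain a geometric number of
spikes (mean ``base_rate * 60 / burst_rate``), and spikes inside a burst are
near-regular at ``intraburst_freq`` with Gaussian inter-spike jitter. The
long-run rate is exactly ``base_rate`` in expectation.

Coupling is pairwise between ring-adjacent cells of a rosette: a coupled
pair shares spikes copied from a dedicated parent burst train, each parent
spike being shared with probability chosen so that the pair's expected
Jaccard index is ``s / (2*d - s)`` where ``s = coupling_strength`` and ``d``
is the larger coupled degree of the two cells (at most 2 on a ring). The
remaining per-cell rate budget is filled with a private burst train, so every
cell fires at ``base_rate`` in expectation regardless of its degree.

During an epoch whose solution is ``"cbx"``, burst initiation is scaled by
``drug_rate_factor`` and every coupled pair's expected Jaccard index is
scaled by ``drug_coupling_factor`` (the field is literally a multiplicative
JI suppression).
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .datatypes import CellGeometry, Epoch, FrapTrace, RecordingSession

__all__ = ["SynthConfig", "SynthGroundTruth", "generate_recording", "generate_frap"]

#: label that marks a drug epoch in :class:`Epoch.solution`
DRUG_SOLUTION = "cbx"


@dataclass(frozen=True)
class SynthConfig:
    """All knobs of the synthetic slice-recording generator.

    Defaults are calibrated to the study conditions they emulate: 10 frames/s
    for 27 000 frames (45 min), a baseline rate of 0.43 spikes/s of ~1 Hz
    spikes in bursts, a coupled minority of near-neighbour pairs whose
    Jaccard indices average ~0.36 while chance-level pairs stay below 0.1,
    drug-epoch suppression of the rate to 0.06 spikes/s and of the JI by
    15.6 %, and 5.6 um centre-to-centre spacing of neighbouring cells.
    """

    n_slices: int = 1
    cells_per_slice: int | Sequence[int] = 14
    rosette_size: int = 6
    frame_interval: float = 0.1
    n_frames: int = 27_000
    base_rate: float = 0.43
    burst_rate: float = 3.0           # bursts/min
    intraburst_freq: float = 1.0      # Hz
    isi_jitter_sd: float = 2.0        # frames, jitter of intra-burst intervals
    coupling_prob: float = 0.2        # P(adjacent rosette pair is coupled)
    coupling_strength: float = 0.62   # shared fraction of a coupled pair's spikes
    coupling_jitter: int = 0          # frames, timing noise on shared spike copies
    drug_rate_factor: float = 0.06 / 0.43
    drug_coupling_factor: float = 0.844
    amplitude: float = 0.2            # dF/F per spike
    decay_tau: float = 0.4            # s, indicator decay
    noise_sd: float = 2.0             # a.u.
    baseline_intensity: float = 100.0 # a.u., pre-drift resting fluorescence
    bleach_slope: float = 0.005       # fraction/min photobleaching drift
    pixel_size: float = 0.5           # um/pixel
    cell_spacing: float = 5.6         # um, near-neighbour centre distance
    seed: int = 0
    epochs: tuple[tuple[str, int, int, str], ...] | None = None

    def __post_init__(self) -> None:
        if self.n_slices < 1 or self.n_frames < 1 or self.rosette_size < 1:
            raise ValueError("counts must be positive")
        sizes = self.slice_sizes
        if any(s < 1 for s in sizes):
            raise ValueError("cells_per_slice entries must be positive")
        if self.frame_interval <= 0 or self.decay_tau <= 0 or self.pixel_size <= 0:
            raise ValueError("frame_interval, decay_tau and pixel_size must be positive")
        for name in ("base_rate", "burst_rate", "intraburst_freq", "noise_sd",
                     "amplitude", "bleach_slope", "cell_spacing", "isi_jitter_sd",
                     "drug_rate_factor", "drug_coupling_factor"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("coupling_prob", "coupling_strength"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.coupling_jitter < 0:
            raise ValueError("coupling_jitter must be >= 0")

    @property
    def slice_sizes(self) -> list[int]:
        if isinstance(self.cells_per_slice, int):
            return [self.cells_per_slice] * self.n_slices
        sizes = [int(s) for s in self.cells_per_slice]
        if len(sizes) != self.n_slices:
            raise ValueError("cells_per_slice sequence length must equal n_slices")
        return sizes

    def resolved_epochs(self) -> list[Epoch]:
        """Epoch layout; default is a baseline / cbx / washout third-split."""
        if self.epochs is not None:
            return [Epoch(*e) for e in self.epochs]
        third = self.n_frames // 3
        if third == 0:
            return [Epoch("baseline", 0, self.n_frames, "control")]
        return [
            Epoch("baseline", 0, third, "control"),
            Epoch("cbx", third, 2 * third, DRUG_SOLUTION),
            Epoch("washout", 2 * third, self.n_frames, "control"),
        ]

    def replace(self, **kwargs) -> "SynthConfig":
        return dataclasses.replace(self, **kwargs)


@dataclass
class SynthGroundTruth:
    """What the generator actually did, for recovery tests downstream."""

    true_spike_frames: dict[str, np.ndarray]
    coupled_pairs: set[frozenset[str]]
    epochs: list[Epoch]
    rate_multipliers: dict[str, float]          # epoch name -> rate factor
    expected_pair_ji: dict[frozenset[str], float]  # baseline expectation per edge
    config: SynthConfig = None  # type: ignore[assignment]


# ---------------------------------------------------------------------------
# spike-train machinery


def _burst_train_seconds(rng: np.random.Generator, t0: float, t1: float, rate: float,
                         spikes_per_burst: float, isi_mean: float, isi_sd: float,
                         isi_min: float) -> np.ndarray:
    """Burst-renewal spike times (seconds) on [t0, t1) with long-run ``rate``."""
    if rate <= 0 or t1 <= t0:
        return np.empty(0)
    cycle = spikes_per_burst / rate
    # the sweep below advances one ISI past the final spike of each burst,
    # so the effective burst span is N * isi_mean, not (N - 1) * isi_mean
    span = spikes_per_burst * isi_mean
    gap_mean = max(cycle - span, 1e-3)
    out: list[float] = []
    t = t0 + rng.exponential(gap_mean)
    while t < t1:
        n = rng.geometric(min(1.0, 1.0 / spikes_per_burst)) if spikes_per_burst > 1 else 1
        s = t
        for _ in range(n):
            if s >= t1:
                break
            out.append(s)
            s += max(isi_min, rng.normal(isi_mean, isi_sd))
        t = s + rng.exponential(gap_mean)
    return np.asarray(out)


def _spikes_to_frames(times: np.ndarray, frame_interval: float, n_frames: int) -> np.ndarray:
    frames = np.floor(times / frame_interval).astype(np.int64)
    frames = frames[(frames >= 0) & (frames < n_frames)]
    return np.unique(frames)


def _epoch_train(rng: np.random.Generator, cfg: SynthConfig, epochs: list[Epoch],
                 rate_by_epoch: dict[str, float]) -> np.ndarray:
    """Concatenate per-epoch burst trains; returns unique spike frames."""
    m = cfg.base_rate * 60.0 / cfg.burst_rate if cfg.burst_rate > 0 else 1.0
    m = max(m, 1.0)
    isi_mean = 1.0 / cfg.intraburst_freq if cfg.intraburst_freq > 0 else 10 * cfg.frame_interval
    isi_sd = cfg.isi_jitter_sd * cfg.frame_interval
    isi_min = 4 * cfg.frame_interval
    pieces = []
    for ep in epochs:
        rate = rate_by_epoch.get(ep.name, 0.0)
        t0, t1 = ep.start * cfg.frame_interval, ep.end * cfg.frame_interval
        pieces.append(_burst_train_seconds(rng, t0, t1, rate, m, isi_mean, isi_sd, isi_min))
    times = np.concatenate(pieces) if pieces else np.empty(0)
    return _spikes_to_frames(times, cfg.frame_interval, cfg.n_frames)


def _edge_ji_targets(cfg: SynthConfig, edges: list[tuple[int, int]],
                     n_cells: int) -> tuple[np.ndarray, np.ndarray]:
    """Per-edge expected baseline JI and shared-spike inclusion probability.

    With shared rate rho the expected JI of a pair firing at rate r each is
    rho / (2 r - rho); choosing rho = s*r/d (d = max coupled degree) gives
    JI = s / (2 d - s) and keeps every cell's total budget within r.
    The inclusion probability applied to a parent train of rate r is
    pi = rho / r = 2 J / (1 + J).
    """
    deg = np.zeros(n_cells, dtype=int)
    for u, v in edges:
        deg[u] += 1
        deg[v] += 1
    s = cfg.coupling_strength
    ji = np.array([s / (2 * max(deg[u], deg[v]) - s) if s > 0 else 0.0 for u, v in edges])
    pi = 2 * ji / (1 + ji)
    return ji, pi


# ---------------------------------------------------------------------------
# geometry


def _rosette_layout(cfg: SynthConfig, sizes_in_slice: list[int]) -> list[tuple[float, float]]:
    """Cell centres (um) for one slice: rosettes on a wide grid, cells on rings."""
    centers: list[tuple[float, float]] = []
    pitch = 20.0 * cfg.cell_spacing  # rosettes far apart relative to cell spacing
    for g, k in enumerate(sizes_in_slice):
        gx, gy = (g % 4) * pitch, (g // 4) * pitch
        if k == 1:
            centers.append((gx, gy))
            continue
        # chord between ring neighbours equals cell_spacing
        radius = cfg.cell_spacing / (2.0 * np.sin(np.pi / k)) if k > 2 else cfg.cell_spacing / 2.0
        for i in range(k):
            ang = 2.0 * np.pi * i / k
            centers.append((gx + radius * np.cos(ang), gy + radius * np.sin(ang)))
    return centers


def _partition_rosettes(n_cells: int, rosette_size: int) -> list[list[int]]:
    groups = [list(range(i, min(i + rosette_size, n_cells)))
              for i in range(0, n_cells, rosette_size)]
    if len(groups) > 1 and len(groups[-1]) == 1:  # avoid a singleton rosette
        groups[-2].extend(groups.pop())
    return groups


def _ring_edges(group: list[int]) -> list[tuple[int, int]]:
    k = len(group)
    if k < 2:
        return []
    if k == 2:
        return [(group[0], group[1])]
    return [(group[i], group[(i + 1) % k]) for i in range(k)]


# ---------------------------------------------------------------------------
# public API


def generate_recording(config: SynthConfig) -> tuple[RecordingSession, SynthGroundTruth]:
    """Simulate one imaging session with known spike times and coupling.

    Returns the session (fluorescence traces, rectangle geometry, epochs)
    and the ground truth (true spike frames per cell, coupled pairs, epoch
    rate multipliers). Deterministic for a fixed config (including seed).
    """
    cfg = config
    epochs = cfg.resolved_epochs()
    rate_mult = {ep.name: (cfg.drug_rate_factor if ep.solution == DRUG_SOLUTION else 1.0)
                 for ep in epochs}
    root = np.random.SeedSequence(cfg.seed)
    ss_struct, ss_parents, ss_private, ss_noise, ss_jitter = root.spawn(5)
    rng_struct = np.random.default_rng(ss_struct)
    rng_jitter = np.random.default_rng(ss_jitter)

    cell_ids: list[str] = []
    geometry: dict[str, CellGeometry] = {}
    edges_global: list[tuple[int, int]] = []

    for s_idx, n_cells in enumerate(cfg.slice_sizes):
        offset = len(cell_ids)
        slice_id = f"slice{s_idx}"
        ids = [f"s{s_idx}c{i:02d}" for i in range(n_cells)]
        cell_ids.extend(ids)
        groups = _partition_rosettes(n_cells, cfg.rosette_size)
        sizes = [len(g) for g in groups]
        centers = _rosette_layout(cfg, sizes)
        half = 0.45 * cfg.cell_spacing / cfg.pixel_size  # rect half-width, px
        for local, (cx_um, cy_um) in enumerate(centers):
            cx, cy = cx_um / cfg.pixel_size, cy_um / cfg.pixel_size
            geometry[ids[local]] = CellGeometry(
                ids[local],
                round(cx - half), round(cy - half), round(cx + half), round(cy + half),
                cfg.pixel_size, slice_id,
            )
        for group in groups:
            for u, v in _ring_edges(group):
                if cfg.coupling_prob > 0 and rng_struct.random() < cfg.coupling_prob:
                    edges_global.append((offset + u, offset + v))

    n_total = len(cell_ids)
    ji_base, pi_base = _edge_ji_targets(cfg, edges_global, n_total)

    # per-epoch inclusion probability: drug epochs scale the target JI itself
    pi_by_epoch: dict[str, np.ndarray] = {}
    for ep in epochs:
        if ep.solution == DRUG_SOLUTION and len(edges_global):
            j = ji_base * cfg.drug_coupling_factor
            pi_by_epoch[ep.name] = 2 * j / (1 + j)
        else:
            pi_by_epoch[ep.name] = pi_base.copy() if len(edges_global) else pi_base

    # shared (parent-derived) spikes per edge
    shared_frames: dict[str, list[np.ndarray]] = {cid: [] for cid in cell_ids}
    parent_rngs = [np.random.default_rng(s) for s in ss_parents.spawn(max(1, len(edges_global)))]
    epoch_of_frame = np.full(cfg.n_frames, -1, dtype=int)
    for k, ep in enumerate(epochs):
        epoch_of_frame[ep.start:ep.end] = k
    for e_idx, (u, v) in enumerate(edges_global):
        rng_e = parent_rngs[e_idx]
        parent = _epoch_train(rng_e, cfg, epochs,
                              {ep.name: cfg.base_rate * rate_mult[ep.name] for ep in epochs})
        if parent.size == 0:
            continue
        pi_spike = np.array([
            pi_by_epoch[epochs[epoch_of_frame[f]].name][e_idx] if epoch_of_frame[f] >= 0 else 0.0
            for f in parent
        ])
        keep = rng_e.random(parent.size) < pi_spike  # one coin, copied to both cells
        shared = parent[keep]
        for cid_idx in (u, v):
            copy = shared
            if cfg.coupling_jitter > 0 and shared.size:
                copy = shared + rng_jitter.integers(-cfg.coupling_jitter,
                                                    cfg.coupling_jitter + 1, shared.size)
                copy = np.clip(copy, 0, cfg.n_frames - 1)
            shared_frames[cell_ids[cid_idx]].append(copy)

    # private spikes fill each cell's rate budget per epoch
    shared_budget = np.zeros((n_total, len(epochs)))
    for e_idx, (u, v) in enumerate(edges_global):
        for k, ep in enumerate(epochs):
            rho = pi_by_epoch[ep.name][e_idx]  # fraction of cell rate devoted to this edge
            shared_budget[u, k] += rho
            shared_budget[v, k] += rho

    private_rngs = [np.random.default_rng(s) for s in ss_private.spawn(n_total)]
    true_spikes: dict[str, np.ndarray] = {}
    for c_idx, cid in enumerate(cell_ids):
        rates = {ep.name: cfg.base_rate * rate_mult[ep.name]
                 * max(0.0, 1.0 - shared_budget[c_idx, k])
                 for k, ep in enumerate(epochs)}
        private = _epoch_train(private_rngs[c_idx], cfg, epochs, rates)
        allf = [private] + shared_frames[cid]
        true_spikes[cid] = np.unique(np.concatenate(allf)) if allf else np.empty(0, np.int64)

    # forward model: spikes -> fluorescence
    rng_noise = np.random.default_rng(ss_noise)
    decay = float(np.exp(-cfg.frame_interval / cfg.decay_tau))
    t_min = np.arange(cfg.n_frames) * cfg.frame_interval / 60.0
    bleach = np.exp(-cfg.bleach_slope * t_min)
    data = np.empty((cfg.n_frames, n_total))
    from scipy.signal import lfilter
    for c_idx, cid in enumerate(cell_ids):
        impulses = np.zeros(cfg.n_frames)
        impulses[true_spikes[cid]] = 1.0
        kernel = lfilter([1.0], [1.0, -decay], impulses)  # instantaneous rise, exp decay
        f = cfg.baseline_intensity * bleach * (1.0 + cfg.amplitude * kernel)
        data[:, c_idx] = f + rng_noise.normal(0.0, cfg.noise_sd, cfg.n_frames)

    session = RecordingSession(
        traces=pd.DataFrame(data, columns=cell_ids),
        geometry=geometry,
        epochs=epochs,
        pixel_size=cfg.pixel_size,
        frame_interval=cfg.frame_interval,
        metadata={"generator": "zgsync.synthetic", "seed": cfg.seed,
                  "n_slices": cfg.n_slices},
    )
    coupled = {frozenset((cell_ids[u], cell_ids[v])) for u, v in edges_global}
    expected_ji = {frozenset((cell_ids[u], cell_ids[v])): float(ji_base[i])
                   for i, (u, v) in enumerate(edges_global)}
    truth = SynthGroundTruth(true_spikes, coupled, epochs, rate_mult, expected_ji, cfg)
    return session, truth


def generate_frap(mobile_fraction: float, tau: float, bleach_depth: float,
                  config: SynthConfig, *, duration: float = 130.0, dt: float = 0.25,
                  bleach_time: float = 10.0, seed: int | None = None,
                  label: str = "") -> FrapTrace:
    """Simulate a photobleaching recovery trace.

    Pre-bleach plateau at the resting intensity, instantaneous drop to
    ``bleach_depth`` (fraction of the plateau) at ``bleach_time``, then
    single-exponential recovery with time constant ``tau`` towards
    ``bleach_depth + mobile_fraction * (1 - bleach_depth)``, plus additive
    Gaussian noise of ``config.noise_sd`` (a.u.). Seed-deterministic.
    """
    if not (0.0 <= mobile_fraction <= 1.0 and 0.0 <= bleach_depth <= 1.0):
        raise ValueError("mobile_fraction and bleach_depth must lie in [0, 1]")
    if tau <= 0 or duration <= bleach_time or dt <= 0:
        raise ValueError("require tau > 0, dt > 0 and duration > bleach_time")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    times = np.arange(0.0, duration, dt)
    f0 = config.baseline_intensity
    bleach_index = int(np.searchsorted(times, bleach_time))
    trace = np.full(times.size, f0)
    t_post = times[bleach_index:] - times[bleach_index]
    plateau = bleach_depth + mobile_fraction * (1.0 - bleach_depth)
    trace[bleach_index:] = f0 * (bleach_depth
                                 + (plateau - bleach_depth) * (1.0 - np.exp(-t_post / tau)))
    if config.noise_sd > 0:
        trace = trace + rng.normal(0.0, config.noise_sd, trace.size)
    return FrapTrace(times, trace, bleach_index, label=label)
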