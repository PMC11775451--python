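"""Pairwise spike-train synchrony via the Jaccard index.

The Jaccard index (JI) of two spike trains on a shared frame grid is the
number of temporally synchronized spikes divided by the total number of
distinct spikes across the pair: JI = |A ∩ B| / |A ∪ B| for zero tolerance,
and matched / (|A| + |B| - matched) when spikes within ±t frames count as
synchronized (greedy one-to-one matching). 1.0 means identical trains, 0.0
disjoint activity. Chance-level coincidence from the camera's finite frame
rate is estimated with a surrogate in which one train of each pair is
circularly shifted by 1..S frames; genuine coupling survives at shift 0 and
collapses at every non-zero shift. Uncertainty on summary means is
quantified by percentile bootstrap over the resampling unit (connections
for pair-level summaries).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import SpikeTrain

__all__ = [
    "jaccard_index",
    "pairwise_ji",
    "classify_coupled",
    "shift_null",
    "bootstrap_ci",
    "summarize_coupled_ji",
    "SynchronyResult",
    "ShiftNullResult",
    "BootstrapCI",
]

DEFAULT_THRESHOLD = 0.1


def _check_grids(a: SpikeTrain, b: SpikeTrain) -> None:
    if a.n_frames != b.n_frames or a.frame_interval != b.frame_interval:
        raise ValueError("spike trains live on different frame grids")


def _greedy_matches(fa: np.ndarray, fb: np.ndarray, tolerance: int) -> int:
    """One-to-one count of spike pairs within ±tolerance frames.

    Both inputs sorted. The earliest-unmatched-first sweep is a maximum
    matching for interval tolerance on a line (verified against bipartite
    matching in the test suite).
    """
    i = j = matched = 0
    na, nb = fa.size, fb.size
    while i < na and j < nb:
        d = fa[i] - fb[j]
        if abs(d) <= tolerance:
            matched += 1
            i += 1
            j += 1
        elif d < 0:
            i += 1
        else:
            j += 1
    return matched


def jaccard_index(a: SpikeTrain, b: SpikeTrain, tolerance: int = 0) -> float:
    """JI of two trains; NaN if both are empty (undefined, excluded upstream)."""
    _check_grids(a, b)
    if tolerance < 0:
        raise ValueError("tolerance must be >= 0")
    na, nb = a.n_spikes, b.n_spikes
    if na == 0 and nb == 0:
        return float("nan")
    if tolerance == 0:
        inter = np.intersect1d(a.spike_frames, b.spike_frames, assume_unique=True).size
    else:
        inter = _greedy_matches(a.spike_frames, b.spike_frames, tolerance)
    return inter / (na + nb - inter)


@dataclass
class SynchronyResult:
    """Pairwise JI of one cohort, with optional geometry.

    ``ji_matrix`` is symmetric with NaN on the diagonal, for cross-slice
    pairs (never formed) and for undefined pairs (both trains empty).
    """

    cell_ids: list[str]
    ji_matrix: np.ndarray
    slice_of: dict[str, str]
    threshold: float = DEFAULT_THRESHOLD
    tolerance: int = 0
    distances: np.ndarray | None = None   # um, same ordering as ji_matrix
    undefined_pairs: set[frozenset[str]] = field(default_factory=set)

    def pairs_table(self) -> pd.DataFrame:
        """Long-format within-slice pairs: ji, distance, coupled flag."""
        rows = []
        ids = self.cell_ids
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                if self.slice_of[ids[i]] != self.slice_of[ids[j]]:
                    continue
                ji = self.ji_matrix[i, j]
                rows.append({
                    "cell_i": ids[i], "cell_j": ids[j],
                    "slice_id": self.slice_of[ids[i]],
                    "ji": ji,
                    "distance_um": (self.distances[i, j]
                                    if self.distances is not None else np.nan),
                    "coupled": bool(ji > self.threshold) if np.isfinite(ji) else False,
                })
        return pd.DataFrame(rows)

    @property
    def coupled_pairs(self) -> list[tuple[str, str]]:
        return classify_coupled(self)[0]

    @property
    def coupled_cells(self) -> set[str]:
        return classify_coupled(self)[1]


def pairwise_ji(trains: dict[str, SpikeTrain], slice_of: dict[str, str] | None = None,
                tolerance: int = 0, threshold: float = DEFAULT_THRESHOLD,
                distances: np.ndarray | None = None) -> SynchronyResult:
    """JI over all unordered within-slice pairs of a cohort.

    ``slice_of`` maps cell id to slice id; omit it for a single-slice
    recording. Pairs in which both trains are empty are flagged undefined.
    """
    ids = list(trains)
    if len(ids) < 2:
        raise ValueError("need at least 2 cells")
    slice_of = slice_of or {cid: "slice0" for cid in ids}
    n = len(ids)
    mat = np.full((n, n), np.nan)
    undefined: set[frozenset[str]] = set()
    for i in range(n):
        for j in range(i + 1, n):
            if slice_of[ids[i]] != slice_of[ids[j]]:
                continue
            ji = jaccard_index(trains[ids[i]], trains[ids[j]], tolerance)
            if np.isnan(ji):
                undefined.add(frozenset((ids[i], ids[j])))
            mat[i, j] = mat[j, i] = ji
    return SynchronyResult(ids, mat, slice_of, threshold, tolerance,
                           distances, undefined)


def classify_coupled(result: SynchronyResult,
                     threshold: float | None = None) -> tuple[list[tuple[str, str]], set[str]]:
    """Connections with JI strictly above threshold, and the cells they touch."""
    thr = result.threshold if threshold is None else threshold
    ids = result.cell_ids
    pairs: list[tuple[str, str]] = []
    cells: set[str] = set()
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            ji = result.ji_matrix[i, j]
            if np.isfinite(ji) and ji > thr:
                pairs.append((ids[i], ids[j]))
                cells.update((ids[i], ids[j]))
    return pairs, cells


@dataclass
class ShiftNullResult:
    """JI matrices of the same cohort with one train of each pair shifted.

    Shift 0 reproduces the unshifted analysis; shifts 1..S are the surrogate.
    """

    shifts: list[int]
    matrices: list[np.ndarray]
    mean_ji: list[float]          # per shift, over defined within-slice pairs
    frac_above: list[float]       # per shift, fraction of pairs with JI > threshold
    threshold: float = DEFAULT_THRESHOLD

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame({"shift": self.shifts, "mean_ji": self.mean_ji,
                             "frac_above_threshold": self.frac_above})

    @property
    def shifted_mean_ji(self) -> list[float]:
        return [m for s, m in zip(self.shifts, self.mean_ji) if s > 0]


def _circular_shift(train: SpikeTrain, shift: int) -> SpikeTrain:
    frames = np.sort((train.spike_frames + shift) % train.n_frames)
    return SpikeTrain(train.cell_id, frames, train.n_frames, train.frame_interval)


def shift_null(trains: dict[str, SpikeTrain], slice_of: dict[str, str] | None = None,
               max_shift: int = 10, tolerance: int = 0,
               threshold: float = DEFAULT_THRESHOLD) -> ShiftNullResult:
    """Frame-shift surrogate: recompute all pairwise JIs with one train of
    each pair circularly shifted by i frames, for i = 0..max_shift.

    Circular shifting preserves spike counts and burst structure, so any JI
    remaining after a shift is the chance level due to frame binning.
    """
    ids = list(trains)
    if not ids:
        raise ValueError("no trains given")
    n_frames = trains[ids[0]].n_frames
    if not 1 <= max_shift < n_frames:
        raise ValueError("require 1 <= max_shift < n_frames")
    matrices, means, fracs, shifts = [], [], [], []
    for s in range(0, max_shift + 1):
        shifted = {cid: (_circular_shift(t, s) if s else t) for cid, t in trains.items()}
        # shift applies to the second train of each (i, j) pair: compute JI
        # between original train i and shifted train j
        n = len(ids)
        mat = np.full((n, n), np.nan)
        sl = slice_of or {cid: "slice0" for cid in ids}
        for i in range(n):
            for j in range(i + 1, n):
                if sl[ids[i]] != sl[ids[j]]:
                    continue
                mat[i, j] = mat[j, i] = jaccard_index(trains[ids[i]], shifted[ids[j]], tolerance)
        vals = mat[np.triu_indices(n, k=1)]
        vals = vals[np.isfinite(vals)]
        matrices.append(mat)
        means.append(float(np.mean(vals)) if vals.size else float("nan"))
        fracs.append(float(np.mean(vals > threshold)) if vals.size else float("nan"))
        shifts.append(s)
    return ShiftNullResult(shifts, matrices, means, fracs, threshold)


@dataclass(frozen=True)
class BootstrapCI:
    """Percentile bootstrap confidence interval for a mean."""

    statistic: float
    lower: float
    upper: float
    n_resamples: int
    confidence: float
    unit: str = "values"
    seed: int | None = None


def bootstrap_ci(values, n_resamples: int = 10_000, confidence: float = 0.95,
                 seed: int | np.random.Generator | None = None,
                 unit: str = "values") -> BootstrapCI:
    """Percentile CI of the mean by resampling with replacement.

    Draws ``n_resamples`` resamples of the same size as the input, takes the
    mean of each, and returns the (1±confidence)/2 quantiles. Deterministic
    for a fixed seed.
    """
    vals = np.asarray(values, dtype=float).ravel()
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError("bootstrap_ci needs at least one finite value")
    if not 0.0 < confidence < 1.0:
        raise ValueError("confidence must be a fraction in (0, 1)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = vals.size
    means = np.empty(n_resamples)
    chunk = max(1, min(n_resamples, 50_000_000 // max(n, 1)))
    done = 0
    while done < n_resamples:
        k = min(chunk, n_resamples - done)
        idx = rng.integers(0, n, size=(k, n))
        means[done:done + k] = vals[idx].mean(axis=1)
        done += k
    alpha = (1.0 - confidence) / 2.0
    lower, upper = np.quantile(means, [alpha, 1.0 - alpha])
    return BootstrapCI(float(vals.mean()), float(lower), float(upper),
                       n_resamples, confidence, unit,
                       seed if isinstance(seed, int) else None)


def summarize_coupled_ji(result: SynchronyResult, n_resamples: int = 10_000,
                         confidence: float = 0.95,
                         seed: int | np.random.Generator | None = None
                         ) -> tuple[float, BootstrapCI] | None:
    """Mean JI over connections above threshold, with a bootstrap CI.

    Resampling unit is the connection. Returns None if no connection exceeds
    the threshold (flagged empty summary).
    """
    ids = result.cell_ids
    iu = np.triu_indices(len(ids), k=1)
    vals = result.ji_matrix[iu]
    vals = vals[np.isfinite(vals) & (vals > result.threshold)]
    if vals.size == 0:
        return None
    ci = bootstrap_ci(vals, n_resamples, confidence, seed, unit="connections")
    return float(vals.mean()), ci
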