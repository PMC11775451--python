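"""Cell centres from ROIs and centre-to-centre distances in micrometres.

Cells are irregular but roughly rectangular-to-oval; the convention here is
to fit the axis-aligned bounding rectangle of each ROI and take its midpoint
as the cell centre. Distances are Euclidean between centres, scaled by the
pixel size, and are only meaningful within one slice.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .datatypes import CellGeometry
from .synchrony import SynchronyResult, classify_coupled

__all__ = ["fit_rectangle", "pair_distances", "coupled_distance_summary"]


def fit_rectangle(pixels, cell_id: str, pixel_size: float,
                  slice_id: str = "slice0") -> CellGeometry:
    """Bounding rectangle of an ROI given as an (N, 2) array of (x, y) pixel
    coordinates or a 2-D boolean mask (rows = y, columns = x).

    Only the extremes matter: the centre is the rectangle midpoint,
    independent of the mask interior.
    """
    arr = np.asarray(pixels)
    if arr.ndim == 2 and arr.dtype == bool:
        ys, xs = np.nonzero(arr)
        if xs.size == 0:
            raise ValueError(f"empty ROI for cell {cell_id!r}")
    elif arr.ndim == 2 and arr.shape[1] == 2:
        if arr.shape[0] == 0:
            raise ValueError(f"empty ROI for cell {cell_id!r}")
        xs, ys = arr[:, 0], arr[:, 1]
    else:
        raise ValueError("pixels must be an (N, 2) coordinate array or a boolean mask")
    return CellGeometry(cell_id, float(xs.min()), float(ys.min()),
                        float(xs.max()), float(ys.max()), pixel_size, slice_id)


def pair_distances(geometries: list[CellGeometry] | dict[str, CellGeometry]) -> pd.DataFrame:
    """Symmetric centre-to-centre distance matrix in um, indexed by cell id.

    All geometries must share one pixel size (one slice, one calibration);
    cross-slice entries are NaN.
    """
    geoms = list(geometries.values()) if isinstance(geometries, dict) else list(geometries)
    if not geoms:
        raise ValueError("no geometries given")
    by_slice: dict[str, list[CellGeometry]] = {}
    for g in geoms:
        by_slice.setdefault(g.slice_id, []).append(g)
    for sl, gs in by_slice.items():
        if len({g.pixel_size for g in gs}) > 1:
            raise ValueError(f"mismatched pixel_size within slice {sl!r}")
    ids = [g.cell_id for g in geoms]
    n = len(ids)
    mat = np.full((n, n), np.nan)
    index = {g.cell_id: k for k, g in enumerate(geoms)}
    for gs in by_slice.values():
        centers = np.array([g.center_um for g in gs])
        d = squareform(pdist(centers)) if len(gs) > 1 else np.zeros((1, 1))
        rows = [index[g.cell_id] for g in gs]
        mat[np.ix_(rows, rows)] = d
    np.fill_diagonal(mat, 0.0)
    return pd.DataFrame(mat, index=ids, columns=ids)


def coupled_distance_summary(result: SynchronyResult) -> dict | None:
    """Mean ± s.e.m. centre distance of connections with JI above threshold.

    Returns None (flagged empty) when there is no coupled pair, and raises
    if the result carries no distance matrix.
    """
    if result.distances is None:
        raise ValueError("SynchronyResult has no distance matrix attached")
    pairs, _ = classify_coupled(result)
    if not pairs:
        return None
    index = {cid: k for k, cid in enumerate(result.cell_ids)}
    d = np.array([result.distances[index[a], index[b]] for a, b in pairs])
    sem = float(d.std(ddof=1) / np.sqrt(d.size)) if d.size > 1 else 0.0
    return {"mean_um": float(d.mean()), "sem_um": sem, "n": int(d.size)}
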