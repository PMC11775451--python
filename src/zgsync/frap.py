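"""Fluorescence recovery after photobleaching (FRAP) quantification.

A cytosolic dye is bleached in one cell; if the cell shares gap junctions
with its neighbours, unbleached dye flows back in and the signal recovers.
The recovery fraction is measured without any model fit:

    recovery = (F_end - F_post) / (F_pre - F_post)

with F_pre the mean over a pre-bleach window, F_post the minimum shortly
after the bleach, and F_end the mean over the final window of the trace.
0 means no recovery (no cytosolic exchange), 1 full recovery. The measure
is invariant to affine rescaling of the intensities. Group comparisons use
the equal-variance Student's t-test (Welch available behind a flag); an
exponential fit of the recovery is provided as an optional diagnostic.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .datatypes import FrapTrace

__all__ = ["frap_recovery", "fit_recovery", "two_sample_t", "GroupStats"]


def frap_recovery(trace: FrapTrace, post_search: float = 1.0) -> float:
    """Plateau recovery fraction of one bleaching experiment.

    ``post_search`` (s) is the window after the bleach in which the post-bleach
    minimum is taken. Raises when no bleach is visible (F_pre <= F_post).
    The value may fall slightly outside [0, 1] on noisy traces and is
    deliberately reported unclipped.
    """
    t, f = trace.times, trace.intensities
    t_bleach = t[trace.bleach_index]
    pre = f[(t >= t_bleach - trace.pre_window) & (t < t_bleach)]
    post = f[(t >= t_bleach) & (t <= t_bleach + post_search)]
    end = f[t >= t[-1] - trace.post_window]
    if pre.size == 0 or post.size == 0 or end.size == 0:
        raise ValueError("averaging windows fall outside the trace")
    f_pre, f_post, f_end = float(pre.mean()), float(post.min()), float(end.mean())
    if f_pre <= f_post:
        raise ValueError("no bleach detected (pre-bleach level not above post-bleach minimum)")
    return (f_end - f_post) / (f_pre - f_post)


def fit_recovery(trace: FrapTrace) -> dict:
    """Diagnostic single-exponential fit of the post-bleach recovery.

    Fits F(t) = F_post + A * (1 - exp(-t/tau)) from the bleach sample on and
    reports the implied mobile fraction and time constant. Not used by the
    group statistics, which rely on the model-free plateau recovery.
    """
    t, f = trace.times, trace.intensities
    t_bleach = t[trace.bleach_index]
    pre = f[(t >= t_bleach - trace.pre_window) & (t < t_bleach)]
    f_pre = float(pre.mean())
    tp = t[trace.bleach_index:] - t_bleach
    fp = f[trace.bleach_index:]
    f_post = float(fp[: max(1, int(round(1.0 / max(t[1] - t[0], 1e-9))))].min())

    def model(x, amp, tau):
        return f_post + amp * (1.0 - np.exp(-x / tau))

    p0 = (max(f_pre - f_post, 1e-6) * 0.5, max(tp[-1] / 5.0, 1e-3))
    (amp, tau), _ = optimize.curve_fit(model, tp, fp, p0=p0, maxfev=10_000)
    mobile = amp / (f_pre - f_post) if f_pre > f_post else np.nan
    return {"mobile_fraction": float(mobile), "tau_s": float(tau),
            "f_pre": f_pre, "f_post": f_post}


@dataclass(frozen=True)
class GroupStats:
    """Summary of one treatment group's recovery fractions."""

    label: str
    mean: float
    sd: float
    n: int
    values: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.n < 1 or self.sd < 0:
            raise ValueError("need n >= 1 and sd >= 0")
        if self.values is not None and len(self.values) != self.n:
            raise ValueError("n does not match the number of values")

    @classmethod
    def from_values(cls, label: str, values) -> "GroupStats":
        vals = tuple(float(v) for v in values)
        arr = np.asarray(vals)
        sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
        return cls(label, float(arr.mean()), sd, arr.size, vals)

    @classmethod
    def from_summary(cls, label: str, mean: float, sd: float, n: int) -> "GroupStats":
        return cls(label, float(mean), float(sd), int(n))


def two_sample_t(a: GroupStats, b: GroupStats, equal_var: bool = True) -> tuple[float, float]:
    """Two-sided two-sample t-test from group summaries.

    Default is the pooled-variance Student's t; ``equal_var=False`` gives
    Welch's test. Works directly from (mean, sd, n), so printed summary
    statistics are sufficient input. Returns (t, p); a degenerate case with
    zero variance and equal means yields (0, 1).
    """
    if a.n < 2 or b.n < 2:
        raise ValueError("both groups need n >= 2")
    diff = a.mean - b.mean
    if equal_var:
        df = a.n + b.n - 2
        sp2 = ((a.n - 1) * a.sd**2 + (b.n - 1) * b.sd**2) / df
        se = np.sqrt(sp2 * (1.0 / a.n + 1.0 / b.n))
    else:
        va, vb = a.sd**2 / a.n, b.sd**2 / b.n
        se = np.sqrt(va + vb)
        df = ((va + vb) ** 2 / (va**2 / (a.n - 1) + vb**2 / (b.n - 1))
              if va + vb > 0 else a.n + b.n - 2)
    if se == 0:
        return (0.0, 1.0) if diff == 0 else (np.inf * np.sign(diff), 0.0)
    t = diff / se
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(p)
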