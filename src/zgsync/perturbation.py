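"""Before/during drug comparison of spiking rate and synchrony.

The gap-junction-blocker experiment records one cohort across a baseline
epoch, a drug epoch and a washout. Rates are compared per cell across all
epochs; synchrony is compared per connection, restricted to the connections
that were coupled (JI above threshold) at baseline — an uncoupled pair has
no coupling to lose. The change is reported both as a relative percent
change and as an absolute JI difference, with bootstrap CIs over
connections.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import Epoch, SpikeTrain
from .synchrony import BootstrapCI, SynchronyResult, bootstrap_ci, classify_coupled

__all__ = ["epoch_spike_rate", "session_rates", "ji_change", "compare_groups",
           "EpochComparison"]


def epoch_spike_rate(train: SpikeTrain) -> float:
    """Spikes per second of an (already epoch-restricted) train."""
    if train.duration <= 0:
        raise ValueError("zero-duration epoch")
    return train.n_spikes / train.duration


def session_rates(trains_by_epoch: dict[str, dict[str, SpikeTrain]]) -> pd.DataFrame:
    """Per-cell spike rates, one column per epoch."""
    return pd.DataFrame({
        epoch: {cid: epoch_spike_rate(t) for cid, t in trains.items()}
        for epoch, trains in trains_by_epoch.items()
    })


@dataclass
class EpochComparison:
    """Connection-level synchrony change between two epochs of one cohort."""

    connections: pd.DataFrame          # cell_i, cell_j, ji_baseline, ji_drug, changes
    mode: str                          # "relative" or "absolute"
    threshold: float
    mean_relative_pct: float | None
    relative_ci: BootstrapCI | None
    mean_absolute: float | None
    absolute_ci: BootstrapCI | None
    excluded_pairs: list[tuple[str, str]] = field(default_factory=list)

    @property
    def summary_mean(self) -> float | None:
        return self.mean_relative_pct if self.mode == "relative" else self.mean_absolute

    @property
    def summary_ci(self) -> BootstrapCI | None:
        return self.relative_ci if self.mode == "relative" else self.absolute_ci

    def change_histogram(self, bins: int = 20) -> pd.DataFrame:
        """Histogram table of per-connection changes (for the figure-style export)."""
        col = "relative_change_pct" if self.mode == "relative" else "absolute_change"
        vals = self.connections[col].to_numpy()
        counts, edges = np.histogram(vals, bins=bins)
        return pd.DataFrame({"bin_left": edges[:-1], "bin_right": edges[1:],
                             "count": counts})


def ji_change(baseline: SynchronyResult, drug: SynchronyResult,
              mode: str = "relative", n_resamples: int = 10_000,
              confidence: float = 0.95,
              seed: int | np.random.Generator | None = None) -> EpochComparison:
    """Synchrony change on baseline-coupled connections.

    For every connection with baseline JI > threshold:
    absolute change = JI_drug - JI_baseline;
    relative change = 100 * (JI_drug - JI_baseline) / JI_baseline.
    Connections whose drug-epoch JI is undefined (both trains silent) are
    excluded and listed in ``excluded_pairs``. Summaries are means over
    connections with percentile-bootstrap CIs (resampling connections).
    """
    if mode not in ("relative", "absolute"):
        raise ValueError("mode must be 'relative' or 'absolute'")
    if baseline.cell_ids != drug.cell_ids:
        raise ValueError("epochs cover different cells")
    if baseline.threshold != drug.threshold:
        raise ValueError("epochs analyzed with different thresholds")
    pairs, _ = classify_coupled(baseline)
    if not pairs:
        raise ValueError("no baseline-coupled connections")
    index = {cid: k for k, cid in enumerate(baseline.cell_ids)}
    rows, excluded = [], []
    for a, b in pairs:
        i, j = index[a], index[b]
        jb = baseline.ji_matrix[i, j]
        jd = drug.ji_matrix[i, j]
        if not np.isfinite(jd):
            excluded.append((a, b))
            continue
        rows.append({"cell_i": a, "cell_j": b, "ji_baseline": jb, "ji_drug": jd,
                     "absolute_change": jd - jb,
                     "relative_change_pct": 100.0 * (jd - jb) / jb})
    conn = pd.DataFrame(rows)
    if conn.empty:
        return EpochComparison(conn, mode, baseline.threshold,
                               None, None, None, None, excluded)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rel = conn["relative_change_pct"].to_numpy()
    absn = conn["absolute_change"].to_numpy()
    rel_ci = bootstrap_ci(rel, n_resamples, confidence, rng, unit="connections")
    abs_ci = bootstrap_ci(absn, n_resamples, confidence, rng, unit="connections")
    return EpochComparison(conn, mode, baseline.threshold,
                           float(rel.mean()), rel_ci, float(absn.mean()), abs_ci,
                           excluded)


def compare_groups(treated: EpochComparison, control: EpochComparison) -> dict:
    """Side-by-side treated vs control change summaries with a CI-overlap flag."""
    if treated.mode != control.mode or treated.threshold != control.threshold:
        raise ValueError("groups computed with different mode or threshold")
    t_ci, c_ci = treated.summary_ci, control.summary_ci
    overlap = None
    if t_ci is not None and c_ci is not None:
        overlap = bool(t_ci.lower <= c_ci.upper and c_ci.lower <= t_ci.upper)
    return {
        "mode": treated.mode,
        "treated_mean": treated.summary_mean,
        "treated_ci": (t_ci.lower, t_ci.upper) if t_ci else None,
        "treated_n": int(len(treated.connections)),
        "control_mean": control.summary_mean,
        "control_ci": (c_ci.lower, c_ci.upper) if c_ci else None,
        "control_n": int(len(control.connections)),
        "ci_overlap": overlap,
    }
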