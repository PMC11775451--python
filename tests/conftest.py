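"""Shared fixtures: small synthetic sessions generated once per test run."""
from __future__ import annotations

import numpy as np
import pytest

from zgsync.datatypes import SpikeTrain
from zgsync.synthetic import SynthConfig, generate_recording

STUDY_SLICE_SIZES = (39, 33, 29, 24, 20, 17, 14, 10)  # 186 cells, 2413 within-slice pairs


@pytest.fixture(scope="session")
def small_session():
    """One quiet slice: 14 cells, 6600 frames, no coupling, baseline only."""
    cfg = SynthConfig(n_slices=1, cells_per_slice=14, n_frames=6600,
                      coupling_prob=0.0,
                      epochs=(("baseline", 0, 6600, "control"),), seed=11)
    return generate_recording(cfg)


@pytest.fixture(scope="session")
def coupled_session():
    """Study-scale cohort with coupling and a drug epoch (heavy; reused)."""
    cfg = SynthConfig(n_slices=8, cells_per_slice=STUDY_SLICE_SIZES,
                      coupling_prob=0.3, coupling_strength=0.6, seed=3)
    return generate_recording(cfg)


@pytest.fixture(scope="session")
def coupled_detection(coupled_session):
    """Detected spike trains of the study-scale cohort (heavy; reused)."""
    from zgsync.traces import detect_session
    session, _ = coupled_session
    return detect_session(session)


def truth_trains(truth, n_frames: int, frame_interval: float = 0.1) -> dict[str, SpikeTrain]:
    """Ground-truth spike frames as SpikeTrain objects."""
    return {cid: SpikeTrain(cid, frames, n_frames, frame_interval)
            for cid, frames in truth.true_spike_frames.items()}


def match_count(a: np.ndarray, b: np.ndarray, tol: int) -> int:
    """Greedy one-to-one matches between two sorted frame arrays within +-tol."""
    i = j = m = 0
    while i < len(a) and j < len(b):
        d = a[i] - b[j]
        if abs(d) <= tol:
            m += 1
            i += 1
            j += 1
        elif d < 0:
            i += 1
        else:
            j += 1
    return m
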