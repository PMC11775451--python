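"""Pairwise Jaccard synchrony, coupled-pair classification and the shift null.

A coupled minority of near-neighbour pairs shares spikes; the Jaccard index
separates them from chance-level pairs, and circularly shifting one train of
each pair by 1-10 frames shows how much coincidence is expected from frame
binning alone.
"""
import numpy as np

from zgsync import (SynthConfig, classify_coupled, coupled_distance_summary,
                    detect_session, generate_recording, pair_distances,
                    pairwise_ji, shift_null, summarize_coupled_ji)

cfg = SynthConfig(n_slices=2, cells_per_slice=24, n_frames=9000,
                  coupling_prob=0.3, coupling_strength=0.6,
                  epochs=(("baseline", 0, 9000, "control"),), seed=2)
session, truth = generate_recording(cfg)
trains = detect_session(session)
distances = pair_distances(session.geometry).loc[list(trains), list(trains)].to_numpy()
result = pairwise_ji(trains, session.slice_of, distances=distances)

pairs, cells = classify_coupled(result)
mean_ji, ci = summarize_coupled_ji(result, seed=0)
dist = coupled_distance_summary(result)
print(f"{len(pairs)} connections with JI > {result.threshold} "
      f"({len(cells)} of {len(trains)} cells coupled; "
      f"{len(truth.coupled_pairs)} pairs truly coupled)")
print(f"mean coupled JI {mean_ji:.2f} (95% CI {ci.lower:.2f}-{ci.upper:.2f}, "
      f"bootstrap over connections)")
print(f"coupled pairs sit {dist['mean_um']:.1f} um apart (s.e.m. "
      f"{dist['sem_um']:.2f}) - near-neighbour coupling inside rosettes")

null = shift_null(trains, session.slice_of, max_shift=10)
print(f"mean JI: {null.mean_ji[0]:.4f} unshifted vs "
      f"{np.mean(null.shifted_mean_ji):.4f} for shifts 1-10 "
      f"(surviving excess at shift 0 = genuine synchrony, not binning)")
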