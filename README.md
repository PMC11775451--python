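# zgsync

Synchrony analysis of calcium spiking in adrenal **zona glomerulosa (ZG)
rosettes** — a reusable, tested pipeline for slice calcium-imaging cohorts,
with a synthetic-data generator that makes every stage verifiable against
known ground truth.

ZG cells synthesize aldosterone under the control of ~1 Hz intracellular
calcium spikes that cluster into bursts. Cells sit in rosettes (glomeruli) of
a few cells each, and neighbouring cells sometimes spike in synchrony —
a signature of cell–cell coupling, whether through gap junctions or
mechanical linkage. This package quantifies that synchrony and its
pharmacology: it detects spikes in per-cell fluorescence traces, measures
pairwise synchrony with the Jaccard index, separates genuine coupling from
frame-binning coincidence with a shift surrogate, relates coupling to
inter-cell distance, compares baseline against gap-junction-blocker epochs,
and quantifies dye coupling from FRAP (fluorescence recovery after
photobleaching) experiments. It is written for physiologists analysing
slice imaging cohorts and for anyone who needs a well-tested reference
implementation of these statistics.

## The statistic at the core

For two cells with spike-frame sets $A$ and $B$ on a common grid
(10 frames/s), the **Jaccard index**

$$\mathrm{JI} = \frac{|A \cap B|}{|A \cup B|}$$

is 1 for identical spike trains and 0 for fully divergent activity. With a
matching tolerance of $\pm t$ frames, the intersection is replaced by a
greedy one-to-one matching and $\mathrm{JI} = m / (|A| + |B| - m)$ for $m$
matched pairs. Pairs with $\mathrm{JI} > 0.1$ count as **coupled**; chance
coincidence from the camera's finite frame rate is estimated by recomputing
all JIs with one train of each pair circularly shifted by 1–10 frames.
Uncertainty on summary means is quantified by percentile bootstrap
(10,000 resamples over connections). Epoch comparisons report the relative
and absolute JI change of baseline-coupled connections, restricted to
epochs trimmed of their first 60 s (solution exchange). FRAP recovery is
the model-free plateau fraction
$(F_\mathrm{end} - F_\mathrm{post}) / (F_\mathrm{pre} - F_\mathrm{post})$,
compared across treatment groups with Student's *t*.

## Worked example

```python
from zgsync import (SynthConfig, generate_recording, detect_session,
                    pairwise_ji, pair_distances, classify_coupled,
                    summarize_coupled_ji, coupled_distance_summary, shift_null)

cfg = SynthConfig(n_slices=2, cells_per_slice=24, n_frames=9000,
                  coupling_prob=0.3, coupling_strength=0.6,
                  epochs=(("baseline", 0, 9000, "control"),), seed=2)
session, truth = generate_recording(cfg)          # traces + geometry + truth
trains = detect_session(session)                  # dF/F spike detection
dist = pair_distances(session.geometry).loc[list(trains), list(trains)].to_numpy()
result = pairwise_ji(trains, session.slice_of, distances=dist)
```

Running `python examples/02_synchrony_and_shift_null.py` (the same analysis)
prints:

```
16 connections with JI > 0.1 (27 of 48 cells coupled; 16 pairs truly coupled)
mean coupled JI 0.27 (95% CI 0.21-0.33, bootstrap over connections)
coupled pairs sit 5.7 um apart (s.e.m. 0.05) - near-neighbour coupling inside rosettes
mean JI: 0.0290 unshifted vs 0.0218 for shifts 1-10 (surviving excess at shift 0 = genuine synchrony, not binning)
```

Read: of 48 simulated cells, the classifier finds exactly the 16 truly
coupled near-neighbour pairs; their mean JI (0.27) stands far above the
chance level (~0.02), and shifting either train by even one frame collapses
the synchrony — it is not a binning artefact. The other examples cover
detection (`01`), the blocker epoch comparison (`03`) and FRAP group
statistics (`04`). A thin CLI wraps the same operations for file-based use:
`zgsync simulate|detect|ji|shiftnull|perturb|frap|report`.

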