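# Methods

This note documents the models, conventions and design choices behind
`zgsync`: what the synthetic generator simulates and why, how each analysis
stage is defined, which knobs matter, and what passing tests do and do not
establish about real recordings.

## 1. The synthetic recording model

### Spike trains

Each cell fires a **burst-renewal point process**. A cycle is an
exponentially distributed quiescent gap followed by a burst of
`N ~ Geometric` spikes (mean `base_rate * 60 / burst_rate`), spaced
near-regularly at the intra-burst frequency with Gaussian inter-spike
jitter (`isi_jitter_sd`, default 2 frames, floored at 4 frames). The gap
mean is chosen so the long-run rate is exactly `base_rate` in expectation.

Two properties drove this choice over a per-frame Bernoulli process
modulated by a two-state Markov chain: (i) intra-burst spiking in ZG cells
is highly regular at ~1 Hz, whereas Bernoulli-in-burst spiking yields
geometric inter-spike intervals with a 27 % chance of falling at or below
3 frames — colliding with any ~300 ms detector refractory and producing
rasters nothing like slice recordings; (ii) the renewal form makes the
long-run rate exact by construction, which the rate-recovery tests rely
on. The burst/quiescent two-state structure is retained.

Defaults (`SynthConfig`): 10 frames/s (`frame_interval = 0.1 s`),
27,000 frames (45 min), `base_rate = 0.43` spikes/s, `intraburst_freq =
1 Hz`. Burst statistics are not quantified in published work; `burst_rate
= 3/min` (≈ 8.6 spikes per burst, ≈ 8 s bursts, ≈ 12 s gaps) is an
appearance assumption chosen to look like representative raster plots, not
a fit.

### Rosettes, geometry and coupling

Cells are partitioned into rosettes of `rosette_size` (default 6) within
each slice. Rosette centres sit on a wide grid (20 × `cell_spacing`);
cells sit on a ring whose neighbour chord equals `cell_spacing`
(default 5.6 µm, the reported centre-to-centre distance of coupled cells).
Each cell's ROI is an axis-aligned rectangle around its centre; rectangle
coordinates are rounded to whole pixels (`pixel_size` default 0.5 µm/px —
a convention; the imaging calibration is not published).

**Coupling is pairwise between ring-adjacent cells**: each adjacent pair is
coupled with probability `coupling_prob`. Restricting candidates to ring
neighbours encodes the observation that synchrony is confined to
near-neighbour pairs inside rosettes, keeps every coupled distance at
≈ `cell_spacing`, and caps the coupled degree at 2, which is what makes the
per-cell spike-rate budget below satisfiable. A coupled pair shares spikes
via a dedicated **parent burst train** at the cell rate; each parent spike
is copied into *both* cells with probability `pi = 2J/(1+J)` (one coin per
spike, optional `coupling_jitter` frame noise per copy), where the pair's
expected Jaccard index is

```
J = s / (2 d − s),   s = coupling_strength,  d = max coupled degree of the two cells.
```

The remainder of each cell's budget is filled by a private burst train, so
every cell fires at `base_rate` in expectation regardless of degree. For an
isolated coupled pair this reduces to the intuitive `J = s/(2−s)`: `s` is
the fraction of the pair's spikes that are shared.

### Drug epochs

Epochs are named half-open frame intervals with a solution label; the
generator treats `solution == "cbx"` as the blocker epoch and applies two
factors: burst initiation is scaled by `drug_rate_factor` (default
0.06/0.43, the reported rate suppression), and each coupled pair's *target
JI* is scaled by `drug_coupling_factor` (default 0.844, i.e. −15.6 %),
then inverted back to a shared-spike rate. Scaling the JI directly — rather
than scaling `coupling_strength` — makes `drug_coupling_factor` literally a
multiplicative JI suppression; because `J` is nonlinear in `s`, scaling `s`
by 0.844 would suppress the JI by ~21 %, not 15.6 %. Washout epochs revert
to baseline parameters (the slow washout kinetics seen in slices are not
modelled). The default epoch layout splits the recording into
baseline / cbx / washout thirds.

### Fluorescence forward model and noise

Spikes drive an instantaneous-rise, exponential-decay kernel
(`decay_tau = 0.4 s`, `amplitude = 0.2` ΔF/F per spike) on a resting
intensity of 100 a.u., multiplied by an exponential photobleaching drift
(`bleach_slope = 0.005`/min) and read out with additive Gaussian camera
noise (`noise_sd = 2` a.u.). The defaults give a peak signal-to-noise
ratio of 10. Noise is additive and constant, so effective SNR degrades
slowly as the trace bleaches — at 2 %/min the late-recording SNR collapses
and detector false positives explode, which is why the default drift is
the gentler 0.5 %/min plausible for 10 ms widefield exposures.

### Calibration of the coupling defaults

`coupling_prob = 0.2` and `coupling_strength = 0.62` were calibrated once,
analytically, against the two published cohort summaries the generator is
meant to emulate: a coupled-cell fraction of 66/186 ≈ 0.355 (a cell with
two adjacent candidate edges is coupled with probability `1−(1−p)² ≈ 0.36`
at `p = 0.2`) and a mean coupled-connection JI of 0.36 (the degree-1 /
degree-2 edge mixture at `s = 0.62` averages ≈ 0.35, plus ≈ 0.01 chance
coincidence). The default cohort layout used by `scripts/acceptance.py`
(8 slices of 39/33/29/24/20/17/14/10 cells) is a synthetic stand-in chosen
to match the published totals exactly — 186 cells and 2413 within-slice
pair correlations; the real per-slice sizes are not published.

### FRAP traces

`generate_frap` produces a plateau at the resting intensity, an
instantaneous drop to `bleach_depth` (default scenario 0.1, the ~10 % level
seen after bleaching) at 10 s, and single-exponential recovery toward
`bleach_depth + mobile_fraction·(1 − bleach_depth)` with time constant
`tau`, plus additive noise.

## 2. Analysis conventions

- **Frames** are 0-based; **epochs** are half-open `[start, end)`; the
  first 60 s of every epoch are discarded before any statistic
  (`discard_lead`, matching the solution-exchange dead time).
- **Baseline**: rolling 20th-percentile of the raw trace over a 30 s
  window, evaluated every `window/10` frames and linearly interpolated —
  indistinguishable from the per-frame rolling percentile for drifts slow
  relative to the window, at a fraction of the cost.
- **Spike detection** operates on ΔF/F = (F − B)/B. By default the
  indicator tail is stripped first: the innovation
  `d(t) = dFF(t) − exp(−Δt/decay_tau)·dFF(t−1)` turns each transient into
  an isolated impulse of its rise amplitude. Spikes are local maxima of
  `d` with **both** height and prominence ≥ `prominence` (default 0.1
  ΔF/F) and a minimum spacing of 0.3 s. Prominence alone is insufficient
  at SNR 10: slow noise excursions accumulate spurious prominence against
  distant valleys, and stacked in-burst transients mask each other's
  prominence; tail removal plus the height floor fixes both without
  shifting reported frames (for a fast-rising indicator the impulse sits
  on the rise frame). Setting `decay_tau=None` recovers plain peak-finding
  on ΔF/F. Detection thresholds are conventions of this package — the
  original detector was interactive ("automatic under manual
  supervision"); the `qc_table` per-frame overlay export stands in for
  that supervision as an auditable artefact.
- **Jaccard index**: tolerance 0 (same-frame coincidence) by default,
  matching the frame-binning interpretation of chance synchrony; the
  tolerant variant uses greedy earliest-first one-to-one matching, which
  attains the maximum matching for interval tolerance on a line (verified
  against bipartite matching in tests). A pair with two empty trains is
  *undefined* and excluded from every summary rather than counted as 0.
  Pairs are only formed within a slice. Coupling uses strict `JI > 0.1`.
- **Shift null**: circular shift (wraparound) of one train of each pair,
  preserving spike counts; shifts 0–10 are reported, shift 0 reproducing
  the unshifted matrix.
- **Bootstrap**: percentile CI of the mean, 10,000 resamples, resampling
  connections for connection-level summaries and cells for cell-level
  summaries; seeded and deterministic.
- **Epoch comparison**: changes are computed only for connections with
  baseline JI > 0.1 (an uncoupled pair has no coupling to lose). The
  relative percent change is the headline number (matching how the
  suppression is usually quoted); absolute differences are always
  co-reported since the two are easy to conflate. Washout epochs are
  summarized for rates but excluded from JI-change statistics.
- **FRAP recovery**: `F_pre` = mean over 5 s before the bleach, `F_post` =
  minimum within 1 s after it, `F_end` = mean over the final 10 s;
  recovery = `(F_end − F_post)/(F_pre − F_post)`, reported unclipped and
  invariant to affine intensity rescaling. The window lengths are this
  package's convention (the published ones are unstated), configurable on
  `FrapTrace`. Note the minimum statistic is biased low under noise, so
  measured recoveries carry a small upward bias (~+0.02 at SNR 45); the
  optional `fit_recovery` exponential fit is unbiased but model-dependent.
  Group comparisons default to the pooled-variance Student's *t* (as named
  in the source analyses); Welch's test is available via `equal_var=False`.

## 3. Pipeline and reproducibility

`run_pipeline` chains the stages on either a simulated or a loaded session
and emits a `ReproductionReport` in which every entry names the operation
and problem size that produced it, plus full config provenance. One master
seed spawns all per-stage seeds; identical configs give identical reports.
All artefacts are plain CSV/JSON/YAML.

`scripts/acceptance.py` runs the study-scale reproduction: the 186-cell
blocker cohort and 205-cell control cohort at the calibrated defaults
(≈ 30 s total, sizes chosen to match the published cohort scale exactly
while staying desk-runnable), and FRAP groups whose true mobile fractions
form deterministic standardized samples matching the published group
means/SDs (clipped at 0, which together with the minimum-statistic bias
shifts the simulated control group's measured mean slightly above its
target).

## 4. What the tests do and do not show

The generator reproduces the *statistical structure* the analysis assumes:
burst-clustered regular spiking at the published rate, a coupled minority
of near-neighbour pairs with JI ≈ 0.36 against a < 0.1 chance floor,
joint rate/JI suppression in the drug epoch, and partial FRAP recovery. It
does **not** emulate pixel-level movies, motion artefacts, neuropil or
indicator nonlinearity, three-dimensional rosette structure (real
recordings sample a thin optical section, so out-of-plane coupling is
invisible), slow washout kinetics, or mechanically mediated coupling
dynamics. Recovery of ground truth by the pipeline therefore validates the
statistics and their implementation — not the biological detectability of
coupling in any particular real recording. Per-connection JI estimates
inherit burst-level overdispersion, so epoch-change summaries on simulated
cohorts are noticeably noisier than the published cohort CIs; the bootstrap
CIs reported alongside every summary are the honest measure of that
uncertainty.

## 5. Degenerate inputs and numerical edges

Empty spike trains are legal everywhere; a pair of empty trains yields an
undefined (NaN, flagged) JI. `restrict_to_epoch` raises if the discard
lead consumes the whole epoch. `frap_recovery` raises when no bleach is
visible (`F_pre ≤ F_post`). `two_sample_t` returns (0, 1) for identical
zero-variance groups and ±∞ with p = 0 when variance is zero but means
differ. Bootstrap requires at least one finite value. Config validation
rejects non-positive dimensions, probabilities outside [0, 1] and negative
rates at construction time.
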