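"""Gap-junction blocker epoch: rate suppression and synchrony change.

Simulates a 45-min recording whose middle third is perfused with a blocker
(carbenoxolone-style: strong rate suppression, mild synchrony suppression),
then compares spike rates per epoch and the Jaccard index of the
baseline-coupled connections before vs during the drug.
"""
import numpy as np

from zgsync import (PipelineConfig, SynthConfig, run_pipeline)

cfg = SynthConfig(n_slices=3, cells_per_slice=24, seed=3)  # 27,000 frames, 45 min
report = run_pipeline(PipelineConfig(synth=cfg, n_resamples=5000, seed=3))

base = report["mean_rate_baseline"]
drug = report["mean_rate_cbx"]
wash = report["mean_rate_washout"]
print(f"mean activity: {base['value']:.2f} spikes/s at baseline, "
      f"{drug['value']:.2f} during the blocker, {wash['value']:.2f} after washout")
chg = report["ji_change_relative_pct"]
lo, hi = chg["ci"]
print(f"JI of the {chg['n']} baseline-coupled connections changed by "
      f"{chg['value']:+.1f}% (95% CI {lo:+.1f} to {hi:+.1f}) during the blocker")
print(f"(the generator suppressed the rate to "
      f"{cfg.drug_rate_factor:.2%} and the JI to {cfg.drug_coupling_factor:.1%} "
      f"of baseline - a strong rate effect but only a mild synchrony effect)")
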