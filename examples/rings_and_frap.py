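"""Ring-shaped condensate classification and FRAP recovery fitting.

Part 1 renders a droplet population in which 30% are rings (bright shell,
dim core - the signature of target RNA recruited onto the condensate
surface) and measures the ring percentage. Part 2 simulates a bleach-and-
recovery trace with 90% of the recovery reached at 30 s and fits the
single-exponential model.
"""

import numpy as np

import condquant as cq
from condquant.rings import classify_ring, ring_percentage

field = cq.FieldSpec(width_px=700, height_px=700, seed=5, bg_sd=10.0)
droplets = cq.sample_droplets(field, 40, partition_ratios=(7.7,), ring_fraction=0.30)
image, manifest = cq.render_droplet_field(field, droplets)
records, _bg = cq.analyze_droplet_field(image)
calls = [classify_ring(image, r) for r in records]
true_pct = 100 * sum(d.shape_class == "ring" for d in manifest.droplets) / len(manifest.droplets)
print(f"ring percentage: measured {ring_percentage(calls):.1f}% (rendered {true_pct:.1f}%)")

tau = 30.0 / np.log(10.0)  # 90% of recovery at 30 s
truth = cq.FrapTruth(pre_bleach=1.0, post_bleach=0.1, mobile_fraction_true=0.9,
                     tau_s=tau, noise_sd=0.02)
trace = cq.render_frap_series(truth, seed=3)
fit = cq.frap_fit(cq.frap_normalize(trace))
print(f"FRAP fit: mobile fraction {fit.mobile_fraction:.3f} (truth 0.90), "
      f"t_half {fit.t_half_s:.1f} s (truth {tau * np.log(2):.1f} s)")
print(
    "\nA high mobile fraction with a short half-time indicates liquid-like "
    "condensates; gel-like ones show minimal recovery over minutes."
)
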