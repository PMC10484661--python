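"""Two-channel Pearson colocalization with a calibrated target.

Renders a two-channel bacterial field whose sample PCC over the true cell
pixels is constructed to be exactly 0.80 (a condensate reporter channel and
a target-RNA channel), then recovers the coefficient with the analysis-side
measurement over detected cell masks and over the ground-truth masks.
"""

import numpy as np

import condquant as cq

field = cq.FieldSpec(width_px=600, height_px=600, seed=11, bg_sd=5.0)
cells = cq.sample_rod_cells(field, 18)
images, manifest = cq.render_cell_field(field, cells, channels=2, coloc_target_pcc=0.80)

true_mask = np.zeros(images[0].shape, bool)
for c in manifest.cells:
    true_mask |= cq.cell_mask(field, c)
pcc_true = cq.pearson_colocalization(images[0], images[1], true_mask)

result = cq.analyze_cell_field(images[0])
detected_mask = cq.cells_union_mask([c for c in result.cells if c.is_single_rod], images[0].shape)
pcc_detected = cq.pearson_colocalization(images[0], images[1], detected_mask)

print(f"PCC over ground-truth cell pixels: {pcc_true:.3f} (target 0.800)")
print(f"PCC over detected cell masks:      {pcc_detected:.3f}")
print(
    "\nThe mask restricts the correlation to cell pixels; including the "
    "empty background would inflate the coefficient. Detected masks include "
    "a thin blur halo, which dilutes the coefficient slightly."
)
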