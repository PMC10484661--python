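"""Bacterial condensate counting and partition ratios per cell.

Renders rod-shaped cells with 0-3 polar foci (the distribution puts 80% of
cells at 1-2 foci), then runs the cellular recipe: smooth, whole-image
background + 3SD cell detection, single-rod filter, per-cell bright-spot
detection, child-in-parent assignment, foci-subtracted cellular background
and per-focus partition ratios.
"""

import numpy as np

import condquant as cq

field = cq.FieldSpec(width_px=768, height_px=768, seed=7, bg_sd=5.0)
cells = cq.sample_rod_cells(field, 40)
images, manifest = cq.render_cell_field(field, cells)

result = cq.analyze_cell_field(images[0])
rods = [c for c in result.cells if c.is_single_rod]
dist = cq.foci_count_distribution(rods)

print(f"segmented {len(result.cells)} cells, {len(rods)} pass the single-rod filter")
print(f"foci per cell: histogram {dist['histogram']}, mean {dist['mean']:.2f}")
print(f"fraction of cells with 1-2 foci: {dist['fraction_1_2']:.2f}")
ratios = [f.partition_ratio for f in result.foci]
lengths = [c.length_um for c in rods]
print(f"median focus partition ratio: {np.median(ratios):.2f} "
      f"(foci rendered at 4x the cytoplasm level)")
print(f"cell length: mean {np.mean(lengths):.2f} um (drawn from 3.0-4.5 um)")
print(
    "\nEach focus is attributed to the cell containing its centroid; the "
    "partition ratio divides the focus mean by the cytoplasm mean after the "
    "foci region is subtracted from the cell."
)
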