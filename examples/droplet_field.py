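"""In vitro droplet quantification on a synthetic field.

Renders a field of bright RNA condensates (partition ratio 7.7, diameters
1.4-1.8 μm) over a noisy background, then runs the full in vitro recipe:
iterative inverted-threshold background, F_B + 3SD detection with the 0.5 μm
diameter filter, per-droplet partition ratios, and the per-view density.
"""

import condquant as cq

field = cq.FieldSpec(width_px=512, height_px=512, seed=42, bg_mean=100.0, bg_sd=10.0)
droplets = cq.sample_droplets(field, 25, partition_ratios=(7.7,), diameter_range=(1.4, 1.8))
image, manifest = cq.render_droplet_field(field, droplets)

records, background = cq.analyze_droplet_field(image)
density = cq.droplet_density(records, image)
summary = cq.summarize_droplets(records)

print(f"background: mean {background.mean:.2f} ADU, sd {background.sd:.2f} ADU")
print(f"detected {len(records)} of {len(manifest.droplets)} rendered droplets")
print(f"density: {density:.1f} condensates per 4430 um^2 imaging view")
print(summary.round(3))
print(
    "\nThe median partition ratio is the droplet-to-solution intensity ratio; "
    "values below the rendered 7.7 reflect PSF blur diluting the thresholded "
    "object mask (see docs/methods.md)."
)
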