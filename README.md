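# condquant

Quantification of fluorescent RNA condensates in microscopy images — in
vitro droplet fields and condensates ("foci") inside rod-shaped bacteria —
with a synthetic-microscopy generator that validates every analysis stage
against ground truth.

## Who this is for

Labs imaging phase-separated RNA (or protein) condensates with fluorogenic
reporters (e.g. Broccoli/DFHBI-1T, Pepper/HBC620) who want an open, scripted
replacement for commercial point-and-click recipes: condensate detection and
photometry, per-cell condensate counting, colocalization, ring/filled shape
classification, and FRAP mobility analysis — all reproducible from a config
and a seed.

## The measurements

* **Detection** — background mean F_B and standard deviation SD are
  estimated from the condensate-free region by an iterative inverted
  threshold; pixels above **F_B + 3·SD** form objects; components with
  equivalent circular diameter 2·√(area/π) below **0.5 μm** are discarded.
* **Partition ratio** — mean fluorescence inside a condensate divided by
  the mean of the condensate-free background (solution in vitro; the
  foci-subtracted cytoplasm in cells). Reported per droplet/focus.
* **Density** — object count normalized to a fixed imaging view
  (4430 μm² by default).
* **Cellular recipe** — smooth → segment cells at whole-image F_B + 3·SD →
  keep rod-shaped singly detected cells (audit-flagged, not deleted) →
  bright-spot detection inside each cell at the cellular background + 3·SD
  with *grow* and *contrast* refinements → child-in-parent assignment by
  centroid → per-cell foci counts → foci-subtracted cellular background →
  partition ratios; pole-to-pole cell length from the axial intensity
  profile's half-max crossings.
* **Colocalization** — Pearson's correlation coefficient of two channels
  over cell-mask pixels.
* **Ring classification** — core/shell mean-intensity ratio from the radial
  profile; ratio < 0.7 calls a ring (surface-recruited target RNA).
* **FRAP** — single-exponential fit I(t) = A − B·exp(−t/τ) of the
  normalized post-bleach trace; mobile fraction
  (plateau − post)/(pre − post) and half-time τ·ln 2.
* **Statistics** — two-tailed pooled-variance Student's t-test, kinetics
  t90 summarization, aggregation by repeat-content ratio N_CAG/N_total,
  linear fluorescence-to-concentration calibration.

The generator renders all of this synthetically — droplet fields, rod cells
with polar foci, two-channel fields with an exactly calibrated PCC, ring vs
filled profiles, FRAP traces, nucleation-and-growth series — and emits JSON
manifests with every object's truth, so the pipeline is testable end to end
without real data.

## Worked example

```bash
python examples/droplet_field.py
```

```
background: mean 100.06 ADU, sd 10.00 ADU
detected 25 of 25 rendered droplets
density: 100.0 condensates per 4430 um^2 imaging view
                         median      q25      q75  ...  whisker_high     mean   n
partition_ratio           5.828    5.769    5.929  ...         5.991    5.849  25
area_um2                  2.556    2.362    2.962  ...         3.169    2.667  25
equivalent_diameter_um    1.804    1.734    1.942  ...         2.009    1.840  25
mean_intensity          583.157  577.223  593.291  ...       599.502  585.301  25
```

All 25 rendered droplets are recovered; the background estimate matches the
generator's (100, 10). The median measured partition ratio (5.8 against a
rendered 7.7) shows the systematic dilution that PSF blur imposes on
threshold-mask photometry — real instruments do the same to real droplets;
`docs/methods.md` quantifies it. The other examples cover per-cell foci
counting (`cell_foci.py`), colocalization (`colocalization.py`), ring
classification and FRAP (`rings_and_frap.py`), and kinetics plus group
statistics (`kinetics_and_stats.py`).

A thin CLI mirrors the library for shell use:

```bash
condquant simulate droplets --seed 1 --out sim/
condquant quant-droplets sim/droplets.tif --out run/
condquant frap trace.csv --pre-frames 3
```

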