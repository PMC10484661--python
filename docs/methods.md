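# Methods

This note documents the measurement models, the synthetic-data generator,
the study conditions the package is validated under, and the numerical
choices that were genuinely open.

## Measurement model

### Background and detection

The in vitro background estimate is the mean F_B and standard deviation SD
of the condensate-free solution. When no object mask is supplied the
estimate is found by iterated exclusion: threshold at the current
mean + k·SD (k = 3 by default), drop the pixels above it, recompute, until
the retained set is stable (≤ 10 rounds). For a Gaussian background this
truncation biases the mean by −0.04% and the SD by −0.5% — negligible
against the 3·SD detection margin. Detection takes pixels *strictly above*
F_B + k·SD (strict, so that a zero-noise background is never itself
detected and, on blur-free noise-free fields, detected masks equal the true
object masks pixel for pixel), labels connected components (8-connectivity
by default) and discards components with equivalent circular diameter
2·√(area/π) < 0.5 μm. Border-touching components are excluded by default
because their area is censored by the field edge.

Inside a cell the same iteration would fail: foci can occupy a large pixel
fraction of a small cell, making the first mean + 3·SD threshold of the
bimodal mixture higher than the foci themselves, so nothing is ever
excluded. The cellular background iteration is therefore seeded with a
robust median + 3·1.4826·MAD cut (which ignores the bright mode) and then
refined with the usual mean + 3·SD exclusion.

### Partition-ratio photometry and the blur bias

The partition ratio divides the object's mean intensity (over its detected
mask) by the background mean. Under a Gaussian PSF of σ the detected mask
of a bright object extends ~1–2σ beyond the true edge (the threshold sits
far down the blurred edge profile), and the mean over that enlarged mask is
diluted: for a 1.4 μm droplet at ratio 8.9 with σ = 0.08 μm the measured
ratio is ~25% low. This is a property of threshold-mask photometry itself —
commercial recipes and real instruments behave identically — not something
the implementation can correct without deconvolution (out of scope).
Photometric recovery studies therefore run with the generator's blur off
(`psf_sigma_um=0`, and `smooth_sigma_um=0` for the cellular chain, whose
smoothing halo dilutes the cellular background the same way), isolating the
measurement chain; geometric studies (detection, counting, classification,
diameter filtering) run at the realistic default σ = 0.08 μm.

### Cellular recipe details

* *Rod filter*: aspect ratio (ellipse major/minor) ≥ 2, solidity ≥ 0.9,
  area 0.5–10 μm². Rejected cells keep their records with
  `is_single_rod=False` — an audit flag standing in for the manual
  verification step, not silent deletion. For cross-condition **length**
  comparisons the aspect cutoff must sit below the shortest expected
  aspect, otherwise the filter censors the short-cell population and biases
  the comparison; the short-cell analyses here use `rod_aspect_min=1.5`.
* *Bright spots*: threshold at cellular background mean + 3·SD within the
  cell; each component is grown by up to 2 px of constrained dilation over
  pixels above the *whole-cell* mean (foci included — at grow time the
  subtract step has not happened yet; growing over pixels above the
  cytoplasm-only mean would swallow ~half the surrounding noise pixels and
  bias focus photometry by ~−20%). Components with peak / cellular
  background < 1.5 (*contrast*) or measured diameter < 0.5 μm are dropped.
* *Assignment*: a focus belongs to the cell containing its centroid pixel;
  a boundary centroid falls back to greatest overlap area (logged); foci in
  no cell are dropped with a warning.
* *Cellular background*: mean over the cell mask minus the union of foci
  masks; the denominator of every cellular partition ratio.
* *Cell length*: the default report is the distance between the half-max
  crossings of the intensity profile along the mask's principal axis
  (sampled in a ±1 px strip; plateau from the central half; level halfway
  between the image background and the plateau). For a symmetrically
  blurred edge the half-max crossing sits at the true edge, so this
  estimator is unbiased under blur; the raw Feret diameter of the
  thresholded mask (also available) overestimates by ~0.3–0.5 μm.

### Colocalization, rings, FRAP

PCC is computed over cell-mask pixels by default; whole-image PCC is
available but inflates the coefficient through shared empty background.
Ring classification compares the mean over a central core disk (radius
0.4·R around the centroid) with the annulus out to the equivalent radius R;
core/shell < 0.7 calls a ring. The core fraction is deliberately below the
rendered core radius (0.5·R): the detected R is blur-inflated, and 0.4 is
where the measured core/shell distributions of synthetic rings (max ≈ 0.53)
and filled disks (5th percentile ≈ 1.35) separate cleanly; at 0.5 they
touch. Objects under 2 px equivalent radius are returned indeterminate.

FRAP fits I(t) = A − B·exp(−t/τ) to the normalized post-bleach frames
(Levenberg–Marquardt with B ≥ 0, τ > 0; initial guesses: floor from the
first post-bleach frame, plateau from the last three, τ from time to half
range). Mobile fraction = (A − (A−B)) / (pre − (A−B)); values above 1.05
are flagged rather than clipped. A single exponential is the simplest
model consistent with ROI-mean recovery data; reaction–diffusion models
are out of scope.

### Statistics

The two-sample test is the pooled-variance Student's t (Welch available as
a flag), with the two-tailed p from the t distribution at n_a+n_b−2 df;
two identical constant samples give p = 1, constant samples with different
means are an error (the statistic is undefined). Kinetics t90 is the first
crossing of baseline + 0.9·(plateau − baseline), with the plateau the mean
of the final 10% of frames and the baseline the first frame; measuring from
the baseline makes t90 invariant under affine rescaling of the series (for
series rising from zero it coincides with crossing 0.9·plateau). The
repeat-content ratio N_CAG/N_total is (3 × repeat count)/total nucleotides
in % — i.e. repeat *nucleotides* over length; a raw-repeat-count convention
is available. SEM in the ratio aggregation is over condensates within a
construct group (per-replicate grouping is possible by aggregating each
file separately). Concentration calibration is a user-supplied linear fit
(slope ADU/μM, intercept ADU) from known-concentration standards; no
default constants ship.

## Synthetic generator

Defaults emulate a ×100/1.45 NA oil objective with an sCMOS camera:
0.065 μm pixels, Gaussian PSF σ = 0.08 μm (≈ the diffraction-limited width
at 500 nm), Gaussian camera noise (a Poisson+Gaussian model is available;
no camera model is implied by the imaging conditions, so the simpler one is
the default). Intensities are absolute: background b, droplets at p·b for
partition ratio p, cells at b + cytoplasm, foci at cytoplasm level × focus
ratio. Rings have a shell at p·b and a core (inner half of the radius) at
`ring_core_fraction`·shell. Objects are rasterized by pixel-center-inside
tests in a continuous μm frame; optics (blur) are applied before noise;
negative pixels after noise are clipped at zero and flagged in the
manifest. Every render is driven by `numpy.random.default_rng(seed)`, so
identical spec + seed gives bit-identical images.

Populations: droplets are placed by rejection sampling with a surface gap;
rods are capsules placed by capsule-distance rejection with a 0.8 μm
clearance (so blur halos never merge neighbors) and a 0.6 μm border margin;
foci sit on the cell axis, poles first (within 15% of the axis from each
end, mirroring the polar localization of bacterial RNA condensates; a
uniform mode exists). The default foci-count distribution puts 80% of
cells at 1–2 foci. Two-channel fields are built so the sample PCC over the
true cell pixels equals the target exactly: channel 1 standardized over
those pixels (z1), an independent unit field orthogonalized against z1
there (z2), channel 2 = bg + scale·σ₁·(ρ·z1 + √(1−ρ²)·z2); negative pixels
are removed by a uniform (affine, PCC-preserving) shift. FRAP traces follow
the single-exponential truth with Gaussian noise; kinetics series nucleate
droplets as a Poisson process with an exponentially decaying rate
(saturating counts) and grow each droplet's diameter and ratio as
1 − exp(−Δt/τ).

What the generator does **not** emulate: realistic (Airy/vectorial) PSFs,
depth effects or z-stacks, photobleaching outside the FRAP event, cell
division or motion, autofluorescence texture, shot-noise correlations
between channels. Passing tests therefore demonstrate correctness of the
measurement chain under idealized optics and noise — they bound, but do not
measure, performance on real images.

## Validation studies and sizes

All studies run from `condquant.studies` (the acceptance script and the
test suite call the same code). Problem sizes were chosen to give stable
statistics in seconds per study on one CPU: 50 fields × 15 droplets for
detection precision/recall (contrast bg + 10·sd, diameters 0.8–2.0 μm);
~150 droplets per partition-ratio level (2.2, 7.4, 7.7, 8.9; blur off, see
above); 1000 sub-resolution objects (0.2–0.35 μm at the same contrast
class as the detection study) for the diameter filter, plus 200 large
objects re-detected with and without the filter; 300 rods across three
fields for foci counting; ≥10⁴ true-mask pixels per PCC target; 100 noisy
FRAP traces (σ = 0.02, mobile 0.9, τ = 30/ln 10 s); 400 balanced + 1000
at 30% rings; 100 random t-test cases against the scipy reference.

## Known limitations

* Touching droplets are not split (a pure threshold recipe); a watershed
  would be the natural extension.
* Threshold-mask photometry under-reports partition ratios under blur (see
  above); measured ratios are comparable across conditions imaged
  identically, not absolute RNA enrichments.
* The rod filter's thresholds approximate a manual-verification step and
  are deliberately explicit configuration.
* The sub-0.5 μm diameter filter acts on *measured* diameters; very bright
  sub-resolution objects can blur past it, as they would in any
  implementation of the recipe.
* 2D only; no tracking of droplets across kinetics frames (per-frame
  summaries only).
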