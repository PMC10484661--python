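"""End-to-end validation studies against the synthetic generator.

Each function renders synthetic data under the study conditions the package
is validated at, runs the corresponding analysis recipe from scratch, and
returns the recovered quantities together with the problem size. They back
both the acceptance test suite and ``scripts/acceptance.py``.

Study conditions (see the methods note for rationale):

* Detection / counting / classification studies use the realistic generator
  defaults (PSF σ = 0.08 μm, Gaussian camera noise).
* Photometric recovery studies (partition ratios) run without optical blur:
  threshold-mask photometry cannot correct for PSF dilution, which is a
  property of the measurement itself, not of its implementation.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np

from . import (
    CellDetectionConfig,
    DetectionConfig,
    DropletSpec,
    FieldImage,
    FieldSpec,
    FrapTruth,
    analyze_cell_field,
    analyze_droplet_field,
    cell_mask,
    detect_condensates,
    estimate_background,
    pearson_colocalization,
    render_cell_field,
    render_droplet_field,
    render_frap_series,
    sample_droplets,
    sample_rod_cells,
)
from .frap import frap_fit, frap_normalize
from .rings import classify_ring, ring_percentage
from .stats import two_sample_ttest
from .validation import match_by_centroid

__all__ = [
    "droplet_detection_study",
    "partition_recovery_study",
    "diameter_filter_study",
    "foci_count_study",
    "coloc_study",
    "frap_study",
    "ring_study",
    "ttest_study",
    "invariants_study",
]


def droplet_detection_study(seed: int, n_fields: int = 50, droplets_per_field: int = 15) -> dict:
    """Precision/recall of droplet detection on contrasty fields.

    Droplets of 0.8-2.0 μm at peak contrast bg + 10·sd (partition ratio 2 at
    the default bg 100 / sd 10), realistic blur and noise.
    """
    n_tp = n_truth = n_det = 0
    for k in range(n_fields):
        fs = FieldSpec(512, 512, seed=seed + k, bg_sd=10.0)
        drops = sample_droplets(fs, droplets_per_field, partition_ratios=(2.0,),
                                diameter_range=(0.8, 2.0))
        image, _ = render_droplet_field(fs, drops)
        records, _bg = analyze_droplet_field(image)
        m = match_by_centroid([d.center_um for d in drops],
                              [r.centroid_um for r in records], 0.5)
        n_tp += m.n_true_positive
        n_truth += len(drops)
        n_det += len(records)
    return {
        "precision": n_tp / n_det if n_det else float("nan"),
        "recall": n_tp / n_truth,
        "n_truth": n_truth,
        "n_detected": n_det,
    }


def partition_recovery_study(
    seed: int,
    levels: tuple[float, ...] = (2.2, 7.4, 7.7, 8.9),
    min_per_level: int = 100,
) -> dict:
    """Median recovered partition ratio per generator truth level (no blur)."""
    out: dict = {"levels": {}}
    per_field = 30
    n_fields = math.ceil(min_per_level / per_field) + 1
    for li, level in enumerate(levels):
        ratios: list[float] = []
        for k in range(n_fields):
            fs = FieldSpec(512, 512, seed=seed + 1000 * li + k, bg_sd=10.0, psf_sigma_um=0.0)
            drops = sample_droplets(fs, per_field, partition_ratios=(level,),
                                    diameter_range=(1.4, 1.8))
            image, _ = render_droplet_field(fs, drops)
            records, _bg = analyze_droplet_field(image)
            ratios += [r.partition_ratio for r in records]
        med = float(np.median(ratios))
        out["levels"][level] = {
            "median": med,
            "median_error_pct": 100.0 * abs(med - level) / level,
            "n": len(ratios),
        }
    out["max_median_error_pct"] = max(v["median_error_pct"] for v in out["levels"].values())
    return out


def diameter_filter_study(seed: int, n_small: int = 1000, n_big: int = 200) -> dict:
    """The 0.5 μm diameter filter: sub-resolution rejection, large retention."""
    sub_records = 0
    placed_small = 0
    per_field = 100
    k = 0
    while placed_small < n_small:
        fs = FieldSpec(512, 512, seed=seed + k, bg_sd=10.0)
        drops = sample_droplets(fs, per_field, partition_ratios=(2.0,),
                                diameter_range=(0.2, 0.35), min_gap_um=0.8)
        image, _ = render_droplet_field(fs, drops)
        records, _bg = analyze_droplet_field(image)
        sub_records += len(records)
        placed_small += len(drops)
        k += 1
    # Large objects: the diameter filter must never reject a detected
    # component whose true diameter is >= 0.8 um.
    filter_rejected = 0
    placed_big = 0
    cfg_nofilter = DetectionConfig(min_diameter_um=0.0)
    for j in range(math.ceil(n_big / 15)):
        fs = FieldSpec(512, 512, seed=seed + 500 + j, bg_sd=10.0)
        drops = sample_droplets(fs, 15, partition_ratios=(2.0,), diameter_range=(0.8, 2.0))
        image, _ = render_droplet_field(fs, drops)
        bg = estimate_background(image)
        unfiltered = detect_condensates(image, bg, cfg_nofilter)
        filtered = detect_condensates(image, bg, DetectionConfig())
        m_un = match_by_centroid([d.center_um for d in drops],
                                 [r.centroid_um for r in unfiltered], 0.5)
        m_fi = match_by_centroid([d.center_um for d in drops],
                                 [r.centroid_um for r in filtered], 0.5)
        filter_rejected += m_un.n_true_positive - m_fi.n_true_positive
        placed_big += len(drops)
    return {
        "sub_threshold_records": sub_records,
        "n_sub_threshold_objects": placed_small,
        "large_objects_rejected_by_filter": filter_rejected,
        "n_large_objects": placed_big,
    }


def foci_count_study(seed: int, n_cells: int = 300, cells_per_field: int = 100) -> dict:
    """Per-cell foci-count recovery on synthetic single rods."""
    exact = matched = 0
    sum_assigned = sum_truth = 0
    fractions_12 = []
    for k in range(math.ceil(n_cells / cells_per_field)):
        fs = FieldSpec(1024, 1024, seed=seed + k, bg_sd=5.0)
        cells = sample_rod_cells(fs, cells_per_field)
        images, _ = render_cell_field(fs, cells)
        result = analyze_cell_field(images[0])
        rods = [c for c in result.cells if c.is_single_rod]
        m = match_by_centroid([c.center_um for c in cells],
                              [c.centroid_um for c in rods], 0.5)
        for i, j in m.pairs:
            matched += 1
            if rods[j].foci_count == len(cells[i].foci):
                exact += 1
        sum_assigned += sum(c.foci_count for c in rods)
        sum_truth += sum(len(v) for v in result.foci_by_cell.values())
        counts = np.array([c.foci_count for c in rods])
        fractions_12.append(float(np.mean((counts == 1) | (counts == 2))))
    return {
        "exact_fraction": exact / matched if matched else float("nan"),
        "n_matched_cells": matched,
        "assigned_equals_grouped": sum_assigned == sum_truth,
        "fraction_1_2_foci": float(np.mean(fractions_12)),
    }


def coloc_study(seed: int, targets: tuple[float, ...] = (0.55, 0.80)) -> dict:
    """Recovered PCC over the true cell masks for each calibration target."""
    out = {}
    for ti, target in enumerate(targets):
        fs = FieldSpec(600, 600, seed=seed + 10 * ti, bg_sd=5.0)
        cells = sample_rod_cells(fs, 18)
        images, manifest = render_cell_field(fs, cells, channels=2, coloc_target_pcc=target)
        union = np.zeros(images[0].shape, bool)
        for c in manifest.cells:
            union |= cell_mask(fs, c)
        out[target] = {
            "pcc": pearson_colocalization(images[0], images[1], union),
            "n_pixels": int(union.sum()),
        }
    return out


def frap_study(seed: int, n_traces: int = 100) -> dict:
    """FRAP parameter recovery plus the noise-free closed-form case."""
    tau_true = 30.0 / math.log(10.0)  # 90% of recovery at 30 s
    mobiles, taus = [], []
    for k in range(n_traces):
        trace = render_frap_series(FrapTruth(tau_s=tau_true, noise_sd=0.02), seed=seed + k)
        fit = frap_fit(frap_normalize(trace))
        mobiles.append(fit.mobile_fraction)
        taus.append(fit.tau_s)
    t = np.arange(40) * 5.0
    y = 0.1 + 0.8 * (1 - np.exp(-t / 20.0))
    from .frap import FrapTrace

    exact_fit = frap_fit(FrapTrace(np.concatenate([[-5.0], t]), np.concatenate([[1.0], y]), 1))
    return {
        "mean_mobile_fraction": float(np.mean(mobiles)),
        "mean_tau_s": float(np.mean(taus)),
        "tau_true_s": tau_true,
        "n_traces": n_traces,
        "closed_form_mobile_fraction": exact_fit.mobile_fraction,
        "closed_form_t_half_s": exact_fit.t_half_s,
    }


def _ring_calls(seed: int, n: int, ring_fraction: float, per_field: int = 40):
    calls = []
    k = 0
    while len(calls) < n:
        fs = FieldSpec(700, 700, seed=seed + k, bg_sd=10.0)
        drops = sample_droplets(fs, per_field, partition_ratios=(7.7,), ring_fraction=ring_fraction)
        image, manifest = render_droplet_field(fs, drops)
        records, _bg = analyze_droplet_field(image)
        m = match_by_centroid([d.center_um for d in manifest.droplets],
                              [r.centroid_um for r in records], 0.5)
        for i, j in m.pairs:
            call = classify_ring(image, records[j])
            if call.call != "indeterminate":
                calls.append((manifest.droplets[i].shape_class, call))
        k += 1
    return calls[:n]


def ring_study(seed: int, n_balanced: int = 400, n_rate: int = 1000) -> dict:
    """Ring/filled classification accuracy and ring-rate recovery."""
    balanced = _ring_calls(seed, n_balanced, ring_fraction=0.5)
    correct = sum(1 for truth, call in balanced if truth == call.call)
    rate_calls = _ring_calls(seed + 100, n_rate, ring_fraction=0.30)
    true_pct = 100.0 * sum(1 for t, _c in rate_calls if t == "ring") / len(rate_calls)
    measured_pct = ring_percentage([c for _t, c in rate_calls])
    return {
        "classification_accuracy": correct / len(balanced),
        "n_balanced": len(balanced),
        "ring_percentage_measured": measured_pct,
        "ring_percentage_true": true_pct,
        "n_rate": len(rate_calls),
    }


def ttest_study(seed: int, n_cases: int = 100) -> dict:
    """Pooled-variance t-test against scipy's reference, plus the example."""
    from scipy import stats as sps

    rng = np.random.default_rng(seed)
    max_dt = max_dp = 0.0
    for _ in range(n_cases):
        na, nb = rng.integers(2, 40, 2)
        a = rng.normal(rng.uniform(-5, 5), rng.uniform(0.5, 3), na)
        b = rng.normal(rng.uniform(-5, 5), rng.uniform(0.5, 3), nb)
        t, p = two_sample_ttest(a, b)
        rt, rp = sps.ttest_ind(a, b, equal_var=True)
        max_dt = max(max_dt, abs(t - rt))
        max_dp = max(max_dp, abs(p - rp))
    t_ex, p_ex = two_sample_ttest([1, 2, 3], [2, 3, 4])
    return {
        "max_t_deviation": max_dt,
        "max_p_deviation": max_dp,
        "n_cases": n_cases,
        "example_t": t_ex,
        "example_p": p_ex,
    }


def invariants_study(seed: int) -> dict:
    """Scale invariance, threshold monotonicity and seeded reproducibility."""
    fs = FieldSpec(256, 256, seed=seed, bg_sd=10.0)
    drops = sample_droplets(fs, 8, partition_ratios=(5.0,), diameter_range=(0.8, 1.4))
    image, _ = render_droplet_field(fs, drops)
    base, _bg = analyze_droplet_field(image)
    scaled, _ = analyze_droplet_field(FieldImage(image.data * 2.7, image.pixel_size_um))
    scale_ok = len(base) == len(scaled) and all(
        math.isclose(a.partition_ratio, b.partition_ratio, rel_tol=1e-9)
        for a, b in zip(base, scaled)
    )
    bg = estimate_background(image)
    counts = [len(detect_condensates(image, bg, DetectionConfig(sd_multiplier=k)))
              for k in (2.5, 3.0, 4.0, 6.0, 8.0)]
    mono_ok = counts == sorted(counts, reverse=True)
    img2, _ = render_droplet_field(fs, drops)
    repro_ok = bool(np.array_equal(image.data, img2.data))
    fs_c = dataclasses.replace(fs, seed=seed + 1, bg_sd=5.0)
    cells = sample_rod_cells(fs_c, 5)
    c1, _ = render_cell_field(fs_c, cells)
    c2, _ = render_cell_field(fs_c, cells)
    repro_ok = repro_ok and bool(np.array_equal(c1[0].data, c2[0].data))
    return {
        "scale_invariance": scale_ok,
        "threshold_monotonicity": mono_ok,
        "seeded_reproducibility": repro_ok,
        "all_pass": scale_ok and mono_ok and repro_ok,
    }
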