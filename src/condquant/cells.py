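"""Bacterial-cell recipe: cell segmentation, rod filtering, foci detection,
child-in-parent assignment and foci-subtracted cellular backgrounds.

The recipe follows the cellular branch of the measurement pipeline:

1. ``smooth``: Gaussian-smooth the channel used for cell detection.
2. Cell detection: threshold at the whole-image background mean + 3·SD
   (iterative inverted-threshold estimate); connected components above a
   minimum area become cells, with length/width/solidity morphometrics.
3. Rod filter: only rod-shaped, singly detected cells are analyzed further;
   rejected cells are kept with an audit flag instead of being deleted.
4. ``bright spots``: inside each cell, threshold at the *cellular* background
   mean + 3·SD, grow each component while pixels stay above the cellular
   background (``grow``), and discard low-contrast or sub-0.5 μm components
   (``contrast`` and the diameter threshold). Foci are measured on the raw,
   unsmoothed channel.
5. ``child is inside parent``: each focus is assigned to the cell containing
   its centroid; per-cell foci counts come from grouping the assignments.
6. ``subtract``: the cellular background region is the cell mask minus the
   foci masks; its mean intensity is the denominator of every cellular
   partition ratio.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import measure, segmentation

from .droplets import BackgroundEstimate, estimate_background
from .image import FieldImage

__all__ = [
    "CellDetectionConfig",
    "CellRecord",
    "FocusRecord",
    "smooth",
    "segment_cells",
    "filter_single_rod_cells",
    "detect_foci",
    "assign_foci_to_cells",
    "cellular_background",
    "focus_partition_ratio",
    "foci_count_distribution",
    "measure_cell_length",
    "analyze_cell_field",
    "CellFieldResult",
]

logger = logging.getLogger(__name__)


@dataclass
class CellDetectionConfig:
    smooth_sigma_um: float | None = None  # None -> 1 pixel
    cell_sd_multiplier: float = 3.0
    foci_sd_multiplier: float = 3.0
    foci_min_diameter_um: float = 0.5
    min_cell_area_um2: float = 0.5
    max_cell_area_um2: float = 10.0
    rod_aspect_min: float = 2.0
    solidity_min: float = 0.9
    grow_radius_px: int = 2
    contrast_min: float = 1.5
    exclude_border: bool = True

    def __post_init__(self) -> None:
        if self.cell_sd_multiplier <= 0 or self.foci_sd_multiplier <= 0:
            raise ValueError("sd multipliers must be positive")


@dataclass
class CellRecord:
    """One segmented cell with morphometrics and audit flags."""

    label: int
    bbox: tuple[int, int, int, int]
    mask: np.ndarray = field(repr=False)  # local boolean mask within bbox
    area_um2: float = 0.0
    length_um: float = 0.0  # pole-to-pole (max Feret diameter)
    width_um: float = 0.0  # ellipse minor axis
    aspect_ratio: float = 1.0  # ellipse major/minor
    solidity: float = 1.0
    mean_intensity: float = 0.0
    centroid_um: tuple[float, float] = (0.0, 0.0)
    is_single_rod: bool = False
    foci_count: int = 0
    cellular_bg_mean: float = float("nan")
    cellular_bg_sd: float = float("nan")

    def full_mask(self, shape: tuple[int, int]) -> np.ndarray:
        out = np.zeros(shape, dtype=bool)
        r0, c0, r1, c1 = self.bbox
        out[r0:r1, c0:c1] = self.mask
        return out

    def contains_point_px(self, row: float, col: float) -> bool:
        """Whether the pixel under a continuous (row, col) point is in the mask."""
        r0, c0, r1, c1 = self.bbox
        ri, ci = int(math.floor(row)), int(math.floor(col))
        if not (r0 <= ri < r1 and c0 <= ci < c1):
            return False
        return bool(self.mask[ri - r0, ci - c0])


@dataclass
class FocusRecord:
    """One detected intracellular focus (bright spot)."""

    label: int
    parent_cell: int
    area_um2: float
    equivalent_diameter_um: float
    mean_intensity: float
    peak_intensity: float
    centroid_um: tuple[float, float]
    partition_ratio: float = float("nan")
    bbox: tuple[int, int, int, int] | None = None
    mask: np.ndarray | None = field(default=None, repr=False)

    def full_mask(self, shape: tuple[int, int]) -> np.ndarray:
        out = np.zeros(shape, dtype=bool)
        r0, c0, r1, c1 = self.bbox
        out[r0:r1, c0:c1] = self.mask
        return out


def smooth(image: FieldImage, sigma_um: float) -> FieldImage:
    """Gaussian-smoothed copy; sigma 0 returns the input unchanged."""
    if sigma_um < 0:
        raise ValueError("sigma_um must be >= 0")
    if sigma_um == 0:
        return image
    out = image.copy()
    out.data = ndimage.gaussian_filter(
        image.data, sigma=sigma_um / image.pixel_size_um, mode="reflect"
    )
    return out


def segment_cells(
    image: FieldImage,
    config: CellDetectionConfig | None = None,
    *,
    bg: BackgroundEstimate | None = None,
    raw_image: FieldImage | None = None,
) -> list[CellRecord]:
    """Detect cells at the whole-image background mean + k·SD threshold.

    ``image`` should already be smoothed (``analyze_cell_field`` enforces the
    recipe order); ``raw_image`` is used for intensity measurement when the
    detection image is a smoothed copy. Length is the component's maximum
    Feret diameter (pole-to-pole extent); width is the ellipse-fit minor
    axis, used only for the rod-shape filter.
    """
    config = config or CellDetectionConfig()
    px = image.pixel_size_um
    meas = (raw_image or image).data
    if bg is None:
        bg = estimate_background(image, sd_multiplier=config.cell_sd_multiplier)
    mask = image.data > bg.threshold(config.cell_sd_multiplier)
    labels = measure.label(mask, connectivity=2)
    h, w = image.shape
    cells: list[CellRecord] = []
    for rp in measure.regionprops(labels, intensity_image=meas):
        if config.exclude_border:
            r0, c0, r1, c1 = rp.bbox
            if r0 == 0 or c0 == 0 or r1 == h or c1 == w:
                continue
        area_um2 = rp.area * px * px
        if area_um2 < config.min_cell_area_um2:
            continue
        minor = rp.axis_minor_length * px
        major = rp.axis_major_length * px
        cy, cx = rp.centroid
        cells.append(
            CellRecord(
                label=int(rp.label),
                bbox=tuple(rp.bbox),
                mask=rp.image.copy(),
                area_um2=float(area_um2),
                length_um=float(rp.feret_diameter_max * px),
                width_um=float(minor),
                aspect_ratio=float(major / minor) if minor > 0 else float("inf"),
                solidity=float(rp.solidity),
                mean_intensity=float(rp.intensity_mean),
                centroid_um=((cx + 0.5) * px, (cy + 0.5) * px),
            )
        )
    return cells


def filter_single_rod_cells(
    cells: list[CellRecord], config: CellDetectionConfig | None = None
) -> list[CellRecord]:
    """Flag rod-shaped singly detected cells; keep rejects for auditing.

    A cell passes when aspect_ratio >= rod_aspect_min, solidity >=
    solidity_min and its area lies within the configured bounds (a merged
    pair of cells fails on solidity or area). All cells are returned with
    ``is_single_rod`` set; callers select on the flag.
    """
    config = config or CellDetectionConfig()
    for c in cells:
        c.is_single_rod = (
            c.aspect_ratio >= config.rod_aspect_min
            and c.solidity >= config.solidity_min
            and config.min_cell_area_um2 <= c.area_um2 <= config.max_cell_area_um2
        )
    return cells


def _cell_background(
    data: np.ndarray, cell_mask_local: np.ndarray, sd_multiplier: float, max_iter: int = 10
) -> BackgroundEstimate:
    """Iterative exclusion background restricted to the cell's own pixels.

    Inside a small cell the foci can cover a large pixel fraction, so a
    mean+k·SD iteration started from all pixels may never exclude anything
    (the mixture SD is huge). The iteration is therefore seeded with a robust
    median + k·1.4826·MAD threshold, which ignores the bright mode, and then
    refined with the usual mean+k·SD exclusion until stable.
    """
    vals_mask = cell_mask_local.copy()
    if not vals_mask.any():
        raise ValueError("cell has no interior pixels")
    all_vals = data[vals_mask]
    med = np.median(all_vals)
    mad_sd = 1.4826 * np.median(np.abs(all_vals - med))
    keep = vals_mask & (data < med + sd_multiplier * mad_sd) if mad_sd > 0 else vals_mask.copy()
    if not keep.any():
        keep = vals_mask.copy()
    for _ in range(max_iter):
        vals = data[keep]
        thr = vals.mean() + sd_multiplier * vals.std()
        new_keep = vals_mask & (data < thr)
        if not new_keep.any():
            break
        if np.array_equal(new_keep, keep):
            break
        keep = new_keep
    vals = data[keep]
    return BackgroundEstimate(float(vals.mean()), float(vals.std()), int(vals.size))


def detect_foci(
    image: FieldImage, cell: CellRecord, config: CellDetectionConfig | None = None
) -> list[FocusRecord]:
    """Bright-spots detection inside one cell.

    Thresholds at the cellular background mean + k·SD (iterative exclusion
    restricted to the cell), grows each component by up to ``grow_radius_px``
    over pixels still above the cellular background mean, then drops
    components failing the contrast (peak / cellular background >=
    ``contrast_min``) or minimum-diameter tests. Foci spanning the cell
    boundary are clipped to the cell mask. The cellular background estimate
    is stored on the cell record (and later refined by ``cellular_background``
    once foci masks are known).
    """
    config = config or CellDetectionConfig()
    px = image.pixel_size_um
    r0, c0, r1, c1 = cell.bbox
    pad = config.grow_radius_px
    R0, C0 = max(r0 - pad, 0), max(c0 - pad, 0)
    R1, C1 = min(r1 + pad, image.shape[0]), min(c1 + pad, image.shape[1])
    local = image.data[R0:R1, C0:C1]
    cmask = np.zeros(local.shape, dtype=bool)
    cmask[r0 - R0 : r1 - R0, c0 - C0 : c1 - C0] = cell.mask

    cbg = _cell_background(local, cmask, config.foci_sd_multiplier)
    cell.cellular_bg_mean = cbg.mean
    cell.cellular_bg_sd = cbg.sd

    spot_mask = cmask & (local > cbg.threshold(config.foci_sd_multiplier))
    labels = measure.label(spot_mask, connectivity=2)
    if labels.max() == 0:
        return []
    if config.grow_radius_px > 0:
        # Grow into the bright skirt only: at this stage the foci region has
        # not been subtracted yet, so the reference level is the whole-cell
        # mean (foci included). Plain cytoplasm noise sits well below it.
        cell_mean = float(local[cmask].mean())
        grown = segmentation.expand_labels(labels, distance=config.grow_radius_px)
        grown[~(cmask & (local > cell_mean))] = 0
        grown[spot_mask] = labels[spot_mask]  # original pixels always kept
        labels = grown

    foci: list[FocusRecord] = []
    for rp in measure.regionprops(labels, intensity_image=local):
        area_um2 = rp.area * px * px
        diam = 2.0 * math.sqrt(area_um2 / math.pi)
        if diam < config.foci_min_diameter_um:
            continue
        if cbg.mean > 0 and rp.intensity_max / cbg.mean < config.contrast_min:
            continue
        cy, cx = rp.centroid
        br0, bc0, br1, bc1 = rp.bbox
        foci.append(
            FocusRecord(
                label=int(rp.label),
                parent_cell=cell.label,
                area_um2=float(area_um2),
                equivalent_diameter_um=float(diam),
                mean_intensity=float(rp.intensity_mean),
                peak_intensity=float(rp.intensity_max),
                centroid_um=((cx + C0 + 0.5) * px, (cy + R0 + 0.5) * px),
                bbox=(br0 + R0, bc0 + C0, br1 + R0, bc1 + C0),
                mask=rp.image.copy(),
            )
        )
    return foci


def assign_foci_to_cells(
    foci: list[FocusRecord],
    cells: list[CellRecord],
    *,
    pixel_size_um: float,
    image_shape: tuple[int, int] | None = None,
) -> dict[int, list[FocusRecord]]:
    """Child-in-parent assignment by focus centroid.

    Each focus is assigned to the cell whose mask contains its centroid
    pixel; when the centroid pixel belongs to no cell but the focus overlaps
    one or more cells, the cell with the greatest overlap area wins (boundary
    tie, logged). Foci inside no cell are dropped with a warning. Per-cell
    ``foci_count`` is set from the grouped assignments.
    """
    px = pixel_size_um
    mapping: dict[int, list[FocusRecord]] = {c.label: [] for c in cells}
    for c in cells:
        c.foci_count = 0
    for f in foci:
        col = f.centroid_um[0] / px
        row = f.centroid_um[1] / px
        parent = None
        for c in cells:
            if c.contains_point_px(row, col):
                parent = c
                break
        if parent is None and image_shape is not None and f.bbox is not None:
            fmask = f.full_mask(image_shape)
            best, best_overlap = None, 0
            for c in cells:
                ov = int(np.count_nonzero(fmask & c.full_mask(image_shape)))
                if ov > best_overlap:
                    best, best_overlap = c, ov
            if best is not None:
                logger.info(
                    "focus %d centroid on boundary; assigned to cell %d by overlap",
                    f.label,
                    best.label,
                )
                parent = best
        if parent is None:
            logger.warning("focus %d lies in no cell; dropped", f.label)
            continue
        f.parent_cell = parent.label
        parent.foci_count += 1
        mapping[parent.label].append(f)
    return mapping


def cellular_background(
    image: FieldImage, cell: CellRecord, foci_in_cell: list[FocusRecord]
) -> float:
    """Mean intensity over the cell mask minus the union of foci masks.

    This is the ``subtract`` step: the cellular background region is the
    cell's cytoplasm with the condensates removed. Stored on the record.
    """
    shape = image.shape
    region = cell.full_mask(shape)
    for f in foci_in_cell:
        region &= ~f.full_mask(shape)
    if not region.any():
        raise ValueError(f"foci cover the whole of cell {cell.label}")
    cell.cellular_bg_mean = float(image.data[region].mean())
    return cell.cellular_bg_mean


def focus_partition_ratio(focus: FocusRecord, cellular_bg_mean: float) -> float:
    """Focus mean intensity over the foci-subtracted cellular background."""
    if not (cellular_bg_mean > 0):
        raise ValueError("cellular background mean must be positive")
    focus.partition_ratio = focus.mean_intensity / cellular_bg_mean
    return focus.partition_ratio


def foci_count_distribution(cells: list[CellRecord]) -> dict:
    """Per-cell foci-count histogram and the 1–2 foci fraction."""
    counts = np.array([c.foci_count for c in cells], dtype=int)
    if counts.size == 0:
        return {
            "counts": pd.Series(dtype=int),
            "histogram": {},
            "fraction_1_2": float("nan"),
            "median": float("nan"),
            "iqr": (float("nan"), float("nan")),
            "mean": float("nan"),
            "n_cells": 0,
        }
    hist = {int(k): int(v) for k, v in zip(*np.unique(counts, return_counts=True))}
    q25, med, q75 = np.percentile(counts, [25, 50, 75])
    return {
        "counts": pd.Series(counts),
        "histogram": hist,
        "fraction_1_2": float(np.mean((counts == 1) | (counts == 2))),
        "median": float(med),
        "iqr": (float(q25), float(q75)),
        "mean": float(counts.mean()),
        "n_cells": int(counts.size),
    }


def measure_cell_length(
    cell: CellRecord,
    pixel_size_um: float,
    *,
    method: str = "feret",
    image: FieldImage | None = None,
    background_mean: float | None = None,
) -> float:
    """Pole-to-pole cell length in μm.

    ``feret`` (default) is the maximum Feret diameter of the component — a
    pure mask measurement that inherits the threshold halo of the blurred
    edge (a few tenths of a μm of overestimate). ``fwhm`` refines it using
    the intensity image: the profile along the major axis is extracted from a
    narrow strip and the length is the distance between its two half-maximum
    crossings (half-way between ``background_mean`` and the cytoplasm
    plateau). For a symmetrically blurred edge the half-max crossing sits at
    the true edge, so this estimate is unbiased under blur. ``skeleton``
    returns the skeleton extent plus one cell width (useful for bent cells).
    Non-rod cells get the requested measurement with a warning.
    """
    if not cell.is_single_rod:
        logger.warning("cell %d is not flagged as a single rod; length may be unreliable", cell.label)
    if method == "feret":
        rp = measure.regionprops(cell.mask.astype(int))[0]
        return float(rp.feret_diameter_max * pixel_size_um)
    if method == "fwhm":
        if image is None or background_mean is None:
            raise ValueError("method='fwhm' needs the intensity image and a background mean")
        return _fwhm_length(cell, image, background_mean)
    if method == "skeleton":
        from skimage.morphology import skeletonize

        skel = skeletonize(cell.mask)
        n = int(skel.sum())
        if n == 0:
            return float(cell.width_um)
        # Geodesic length approximated by skeleton pixel count; add the cap
        # radii the skeleton cannot reach.
        return float(n * pixel_size_um + cell.width_um)
    raise ValueError(f"unknown method {method!r}")


def _fwhm_length(cell: CellRecord, image: FieldImage, background_mean: float) -> float:
    """Length between the half-max crossings of the axial intensity profile."""
    px = image.pixel_size_um
    rp = measure.regionprops(cell.mask.astype(int))[0]
    # Major-axis unit vector from a PCA of the mask pixel coordinates.
    coords = np.argwhere(cell.mask).astype(float)
    coords -= coords.mean(axis=0)
    _w, vecs = np.linalg.eigh(coords.T @ coords)
    ur, uc = vecs[:, -1]  # eigenvector of the largest eigenvalue, (row, col)
    r0, c0, r1, c1 = cell.bbox
    pad = 6
    R0, C0 = max(r0 - pad, 0), max(c0 - pad, 0)
    R1, C1 = min(r1 + pad, image.shape[0]), min(c1 + pad, image.shape[1])
    window = image.data[R0:R1, C0:C1]
    rows, cols = np.mgrid[R0:R1, C0:C1]
    cr, cc = rp.centroid
    dr, dc = rows - (cr + r0), cols - (cc + c0)
    u = dr * ur + dc * uc  # axial coordinate, px
    v = -dr * uc + dc * ur  # perpendicular coordinate, px
    strip = np.abs(v) <= 1.0
    if not strip.any():
        return float(rp.feret_diameter_max * px)
    ub = np.round(u[strip]).astype(int)
    vals = window[strip]
    lo, hi = ub.min(), ub.max()
    prof = np.full(hi - lo + 1, np.nan)
    for b in range(lo, hi + 1):
        sel = ub == b
        if sel.any():
            prof[b - lo] = vals[sel].mean()
    grid = np.arange(lo, hi + 1, dtype=float)
    # Plateau from the central half of the mask extent.
    half_extent = rp.feret_diameter_max / 4.0
    central = np.abs(grid) <= max(half_extent, 2.0)
    plateau = float(np.nanmedian(prof[central]))
    level = background_mean + 0.5 * (plateau - background_mean)
    if plateau <= background_mean:
        return float(rp.feret_diameter_max * px)
    center_idx = int(np.argmin(np.abs(grid)))

    def crossing(direction: int) -> float:
        i = center_idx
        while 0 <= i + direction < prof.size:
            j = i + direction
            if not np.isnan(prof[j]) and prof[j] < level:
                p_in = prof[i] if not np.isnan(prof[i]) else plateau
                f = (p_in - level) / (p_in - prof[j])
                return grid[i] + f * (grid[j] - grid[i])
            i = j
        return grid[i]

    return float((crossing(+1) - crossing(-1)) * px)


@dataclass
class CellFieldResult:
    """Everything the cellular recipe produces for one field."""

    cells: list[CellRecord]
    foci: list[FocusRecord]
    background: BackgroundEstimate
    foci_by_cell: dict[int, list[FocusRecord]]


def analyze_cell_field(
    image: FieldImage, config: CellDetectionConfig | None = None
) -> CellFieldResult:
    """Full cellular recipe in the prescribed order.

    smooth → segment cells → rod filter → bright spots per rod → child-in-
    parent assignment → foci-subtracted cellular backgrounds → partition
    ratios. Foci are detected and measured on the raw (unsmoothed) channel.
    """
    config = config or CellDetectionConfig()
    sigma = config.smooth_sigma_um if config.smooth_sigma_um is not None else image.pixel_size_um
    smoothed = smooth(image, sigma)
    bg = estimate_background(smoothed, sd_multiplier=config.cell_sd_multiplier)
    cells = segment_cells(smoothed, config, bg=bg, raw_image=image)
    filter_single_rod_cells(cells, config)
    rods = [c for c in cells if c.is_single_rod]
    foci: list[FocusRecord] = []
    next_label = 1
    for cell in rods:
        for f in detect_foci(image, cell, config):
            f.label = next_label
            next_label += 1
            foci.append(f)
    mapping = assign_foci_to_cells(
        foci, rods, pixel_size_um=image.pixel_size_um, image_shape=image.shape
    )
    for cell in rods:
        in_cell = mapping.get(cell.label, [])
        cellular_background(image, cell, in_cell)
        for f in in_cell:
            focus_partition_ratio(f, cell.cellular_bg_mean)
        cell.length_um = measure_cell_length(
            cell, image.pixel_size_um, method="fwhm", image=image, background_mean=bg.mean
        )
    return CellFieldResult(cells=cells, foci=foci, background=bg, foci_by_cell=mapping)
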