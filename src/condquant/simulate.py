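"""Synthetic fluorescence-microscopy generator with ground-truth manifests.

Every analysis stage in this package is validated against fields rendered
here: in vitro droplet fields (bright near-circular condensates on a dim
background), rod-shaped bacterial cells with polar foci, two-channel fields
with a calibrated Pearson correlation, ring-shaped versus filled condensate
profiles, FRAP recovery traces, and nucleation-and-growth time series.

Rendering conventions
---------------------
Pixel ``(0, 0)`` sits at the top-left; object centers are given in μm in a
continuous frame where the center of pixel ``(row, col)`` is at
``((col + 0.5) * px, (row + 0.5) * px)``. Masks are rasterized by a
pixel-center-inside test. Object intensities are absolute ADU levels: a
droplet of partition ratio ``p`` on background ``b`` is rendered at ``p * b``
before blur and noise, so the pre-noise mean over its true mask equals its
specified mean exactly. Optics (Gaussian blur of ``psf_sigma_um``) are
applied before camera noise.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage

from .frap import FrapTrace
from .image import FieldImage

__all__ = [
    "GENERATOR_VERSION",
    "RING_CORE_RADIUS_FRACTION",
    "FieldSpec",
    "DropletSpec",
    "CellSpec",
    "FrapTruth",
    "GroundTruthManifest",
    "KineticsTruth",
    "render_droplet_field",
    "render_cell_field",
    "render_frap_series",
    "render_kinetics_series",
    "sample_droplets",
    "sample_rod_cells",
    "polar_foci",
]

GENERATOR_VERSION = "condquant-sim-1.0"

#: Geometric inner radius of a rendered ring droplet, as a fraction of the
#: droplet radius. Matches the default core region used by the ring
#: classifier so that rendered and measured core/shell ratios line up.
RING_CORE_RADIUS_FRACTION = 0.5


# ---------------------------------------------------------------------------
# Specs


@dataclass
class FieldSpec:
    """Imaging-field parameters shared by all render operations.

    Defaults emulate a ×100/1.45 NA oil objective with an sCMOS camera:
    0.065 μm pixels and a Gaussian PSF of σ = 0.08 μm.
    """

    width_px: int = 512
    height_px: int = 512
    pixel_size_um: float = 0.065
    bg_mean: float = 100.0
    bg_sd: float = 10.0
    psf_sigma_um: float = 0.08
    noise_model: str = "gaussian"  # or "poisson_gaussian"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width_px < 32 or self.height_px < 32:
            raise ValueError("field must be at least 32x32 pixels")
        if not (self.pixel_size_um > 0):
            raise ValueError("pixel_size_um must be positive")
        if self.bg_sd < 0 or self.psf_sigma_um < 0:
            raise ValueError("bg_sd and psf_sigma_um must be non-negative")
        if self.noise_model not in ("gaussian", "poisson_gaussian"):
            raise ValueError(f"unknown noise_model {self.noise_model!r}")

    @property
    def width_um(self) -> float:
        return self.width_px * self.pixel_size_um

    @property
    def height_um(self) -> float:
        return self.height_px * self.pixel_size_um


@dataclass
class DropletSpec:
    """One simulated condensate (in vitro droplet or intracellular focus)."""

    center_um: tuple[float, float]
    diameter_um: float
    partition_ratio_true: float
    shape_class: str = "filled"  # or "ring"
    ring_core_fraction: float = 0.2

    def __post_init__(self) -> None:
        self.center_um = tuple(float(v) for v in self.center_um)
        if not (self.diameter_um > 0):
            raise ValueError("diameter_um must be positive")
        if self.partition_ratio_true < 1:
            raise ValueError("partition_ratio_true must be >= 1")
        if self.shape_class not in ("filled", "ring"):
            raise ValueError(f"unknown shape_class {self.shape_class!r}")
        if not (0 <= self.ring_core_fraction < 1):
            raise ValueError("ring_core_fraction must be in [0, 1)")

    @property
    def radius_um(self) -> float:
        return self.diameter_um / 2.0


@dataclass
class CellSpec:
    """One rod-shaped bacterium: a spherocylinder with optional foci.

    ``cytoplasm_intensity`` is the cytoplasm level *above* background (ADU);
    each focus is rendered at ``(bg + cytoplasm) × partition_ratio_true``.
    Focus centers are positioned in the cell's own axial frame and must lie
    inside the cell mask.
    """

    center_um: tuple[float, float]
    length_um: float
    width_um: float
    orientation_deg: float = 0.0
    cytoplasm_intensity: float = 200.0
    foci: list[DropletSpec] = field(default_factory=list)
    second_channel_scale: float = 1.0

    def __post_init__(self) -> None:
        self.center_um = tuple(float(v) for v in self.center_um)
        if not (self.width_um > 0) or self.length_um < self.width_um:
            raise ValueError("require length_um >= width_um > 0")

    @property
    def axis_unit(self) -> tuple[float, float]:
        a = math.radians(self.orientation_deg)
        return (math.cos(a), math.sin(a))

    def pole_points(self) -> tuple[np.ndarray, np.ndarray]:
        """End points of the central segment (caps extend width/2 beyond)."""
        ux, uy = self.axis_unit
        half = max(self.length_um - self.width_um, 0.0) / 2.0
        c = np.asarray(self.center_um, dtype=float)
        return c - half * np.array([ux, uy]), c + half * np.array([ux, uy])

    def axis_point(self, frac: float) -> tuple[float, float]:
        """A point on the pole-to-pole axis; frac 0 and 1 are the two tips."""
        ux, uy = self.axis_unit
        s = (frac - 0.5) * self.length_um
        return (self.center_um[0] + s * ux, self.center_um[1] + s * uy)


@dataclass
class FrapTruth:
    """Ground truth for a single-exponential FRAP recovery trace."""

    pre_bleach: float = 1.0
    post_bleach: float = 0.1
    mobile_fraction_true: float = 0.9
    tau_s: float = 13.0288  # 90% of recovery reached at ~30 s
    frame_interval_s: float = 5.0
    n_frames: int = 40
    noise_sd: float = 0.02
    n_pre_frames: int = 3

    def __post_init__(self) -> None:
        if not (self.post_bleach < self.pre_bleach):
            raise ValueError("post_bleach must be below pre_bleach")
        if not (0 <= self.mobile_fraction_true <= 1):
            raise ValueError("mobile_fraction_true must be in [0, 1]")
        if not (self.tau_s > 0 and self.frame_interval_s > 0):
            raise ValueError("tau_s and frame_interval_s must be positive")
        if self.n_frames < 5:
            raise ValueError("need at least 5 post-bleach frames")
        if self.n_pre_frames < 1:
            raise ValueError("need at least one pre-bleach frame")

    def recovery(self, t: np.ndarray) -> np.ndarray:
        """Noise-free post-bleach intensity at time ``t`` after the bleach."""
        amp = self.mobile_fraction_true * (self.pre_bleach - self.post_bleach)
        return self.post_bleach + amp * (1.0 - np.exp(-np.asarray(t, float) / self.tau_s))


# ---------------------------------------------------------------------------
# Manifest


def _spec_to_dict(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _spec_to_dict(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, (list, tuple)):
        return [_spec_to_dict(v) for v in obj]
    return obj


@dataclass
class GroundTruthManifest:
    """Lossless record of everything a render call drew.

    One manifest per field; serializes to JSON and round-trips exactly
    (tuples become lists and back).
    """

    field_spec: FieldSpec
    droplets: list[DropletSpec] = field(default_factory=list)
    cells: list[CellSpec] = field(default_factory=list)
    coloc_target_pcc: float | None = None
    clipped_negative: bool = False
    generator_version: str = GENERATOR_VERSION

    def to_dict(self) -> dict:
        return {
            "field_spec": _spec_to_dict(self.field_spec),
            "droplets": [_spec_to_dict(d) for d in self.droplets],
            "cells": [_spec_to_dict(c) for c in self.cells],
            "coloc_target_pcc": self.coloc_target_pcc,
            "clipped_negative": self.clipped_negative,
            "generator_version": self.generator_version,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruthManifest":
        return cls(
            field_spec=FieldSpec(**d["field_spec"]),
            droplets=[DropletSpec(**dd) for dd in d["droplets"]],
            cells=[
                CellSpec(
                    **{
                        **cc,
                        "foci": [DropletSpec(**f) for f in cc.get("foci", [])],
                    }
                )
                for cc in d["cells"]
            ],
            coloc_target_pcc=d.get("coloc_target_pcc"),
            clipped_negative=d.get("clipped_negative", False),
            generator_version=d.get("generator_version", GENERATOR_VERSION),
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def load(cls, path) -> "GroundTruthManifest":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


# ---------------------------------------------------------------------------
# Rasterization helpers


def _pixel_centers(spec: FieldSpec) -> tuple[np.ndarray, np.ndarray]:
    px = spec.pixel_size_um
    x = (np.arange(spec.width_px) + 0.5) * px
    y = (np.arange(spec.height_px) + 0.5) * px
    return np.meshgrid(x, y)  # X[row, col], Y[row, col]


def droplet_mask(spec: FieldSpec, droplet: DropletSpec) -> np.ndarray:
    """Boolean mask of the droplet's true (pre-blur) disk."""
    X, Y = _pixel_centers(spec)
    r2 = (X - droplet.center_um[0]) ** 2 + (Y - droplet.center_um[1]) ** 2
    return r2 <= droplet.radius_um**2


def cell_mask(spec: FieldSpec, cell: CellSpec) -> np.ndarray:
    """Boolean mask of the cell's true spherocylinder."""
    X, Y = _pixel_centers(spec)
    p0, p1 = cell.pole_points()
    d = _dist_to_segment(X, Y, p0, p1)
    return d <= cell.width_um / 2.0


def _dist_to_segment(X, Y, p0, p1) -> np.ndarray:
    vx, vy = p1[0] - p0[0], p1[1] - p0[1]
    vv = vx * vx + vy * vy
    if vv == 0:
        return np.hypot(X - p0[0], Y - p0[1])
    t = ((X - p0[0]) * vx + (Y - p0[1]) * vy) / vv
    t = np.clip(t, 0.0, 1.0)
    return np.hypot(X - (p0[0] + t * vx), Y - (p0[1] + t * vy))


def _segment_segment_distance(a0, a1, b0, b1) -> float:
    """Minimum distance between two 2D segments (for overlap checks)."""
    a0, a1, b0, b1 = (np.asarray(p, float) for p in (a0, a1, b0, b1))

    def pt_seg(p, q0, q1):
        v = q1 - q0
        vv = float(v @ v)
        if vv == 0:
            return float(np.hypot(*(p - q0)))
        t = float(np.clip((p - q0) @ v / vv, 0.0, 1.0))
        return float(np.hypot(*(p - (q0 + t * v))))

    def intersects(p0, p1, q0, q1):
        def orient(a, b, c):
            return np.sign((b[0] - a[0]) * (c[1] - a[1]) - (b[1] - a[1]) * (c[0] - a[0]))

        return (
            orient(p0, p1, q0) * orient(p0, p1, q1) < 0
            and orient(q0, q1, p0) * orient(q0, q1, p1) < 0
        )

    if intersects(a0, a1, b0, b1):
        return 0.0
    return min(
        pt_seg(a0, b0, b1),
        pt_seg(a1, b0, b1),
        pt_seg(b0, a0, a1),
        pt_seg(b1, a0, a1),
    )


def _droplet_inside_field(spec: FieldSpec, d: DropletSpec) -> bool:
    x, y = d.center_um
    r = d.radius_um
    return (x - r >= 0 and y - r >= 0 and x + r <= spec.width_um and y + r <= spec.height_um)


def _apply_optics_and_noise(
    spec: FieldSpec, signal: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, bool]:
    img = signal
    if spec.psf_sigma_um > 0:
        img = ndimage.gaussian_filter(img, sigma=spec.psf_sigma_um / spec.pixel_size_um, mode="nearest")
    if spec.noise_model == "poisson_gaussian":
        img = rng.poisson(np.clip(img, 0, None)).astype(float)
        if spec.bg_sd > 0:
            img = img + rng.normal(0.0, spec.bg_sd, img.shape)
    else:
        if spec.bg_sd > 0:
            img = img + rng.normal(0.0, spec.bg_sd, img.shape)
        else:
            img = img.copy()
    clipped = bool(np.any(img < 0))
    if clipped:
        np.clip(img, 0, None, out=img)
    return img, clipped


# ---------------------------------------------------------------------------
# Render operations


def render_droplet_field(
    field_spec: FieldSpec,
    droplets: Sequence[DropletSpec],
    *,
    allow_overlap: bool = False,
) -> tuple[FieldImage, GroundTruthManifest]:
    """Render an in vitro droplet field and its ground-truth manifest.

    Filled droplets are drawn at ``bg_mean × partition_ratio_true``; rings are
    drawn with a shell at that level and a core (inner half of the radius) at
    ``ring_core_fraction × shell``. The disk/annulus is then blurred by the
    PSF and camera noise is added per ``noise_model``.
    """
    rng = np.random.default_rng(field_spec.seed)
    signal = np.full((field_spec.height_px, field_spec.width_px), float(field_spec.bg_mean))
    masks = []
    for d in droplets:
        if not _droplet_inside_field(field_spec, d):
            raise ValueError(f"droplet at {d.center_um} (d={d.diameter_um} um) lies outside the field")
        m = droplet_mask(field_spec, d)
        if not allow_overlap and any(np.any(m & prev) for prev in masks):
            raise ValueError(f"droplet at {d.center_um} overlaps a previous droplet (pass allow_overlap=True)")
        level = field_spec.bg_mean * d.partition_ratio_true
        signal[m] = level
        if d.shape_class == "ring":
            core = DropletSpec(d.center_um, d.diameter_um * RING_CORE_RADIUS_FRACTION, 1.0)
            signal[droplet_mask(field_spec, core)] = d.ring_core_fraction * level
        masks.append(m)
    img, clipped = _apply_optics_and_noise(field_spec, signal, rng)
    manifest = GroundTruthManifest(field_spec, droplets=list(droplets), clipped_negative=clipped)
    return FieldImage(img, field_spec.pixel_size_um), manifest


def render_cell_field(
    field_spec: FieldSpec,
    cells: Sequence[CellSpec],
    *,
    channels: int = 1,
    coloc_target_pcc: float | None = None,
    allow_overlap: bool = False,
) -> tuple[list[FieldImage], GroundTruthManifest]:
    """Render a bacterial field in one or two channels.

    Cells are spherocylinders at ``bg + cytoplasm_intensity``; each focus is a
    disk (clipped to its cell) at ``cytoplasm level × partition_ratio_true``.

    With ``channels=2`` the second channel is constructed so that the sample
    Pearson correlation of the two channels over the union of the true cell
    masks equals ``coloc_target_pcc`` exactly: channel 1 is standardized over
    the cell pixels (``z1``), an independent unit-variance noise field is
    orthogonalized against ``z1`` over the same pixels (``z2``), and channel 2
    is ``bg + scale·σ₁·(ρ·z1 + √(1−ρ²)·z2)``. With ``coloc_target_pcc=1`` and
    zero noise, channel 2 is an exact affine transform of channel 1.
    """
    if channels not in (1, 2):
        raise ValueError("channels must be 1 or 2")
    rng = np.random.default_rng(field_spec.seed)
    signal = np.full((field_spec.height_px, field_spec.width_px), float(field_spec.bg_mean))
    cell_masks = []
    for c in cells:
        m = cell_mask(field_spec, c)
        if not m.any():
            raise ValueError(f"cell at {c.center_um} rasterizes to an empty mask")
        if not allow_overlap and any(np.any(m & prev) for prev in cell_masks):
            raise ValueError(f"cell at {c.center_um} overlaps a previous cell (pass allow_overlap=True)")
        cyto_level = field_spec.bg_mean + c.cytoplasm_intensity
        signal[m] = cyto_level
        for f in c.foci:
            fm = droplet_mask(field_spec, f)
            if not m[_nearest_pixel(field_spec, f.center_um)]:
                raise ValueError(f"focus at {f.center_um} lies outside its parent cell")
            signal[fm & m] = cyto_level * f.partition_ratio_true
        cell_masks.append(m)
    ch1, clipped = _apply_optics_and_noise(field_spec, signal, rng)
    images = [FieldImage(ch1, field_spec.pixel_size_um, channel="488")]

    if channels == 2:
        union = np.zeros_like(signal, dtype=bool)
        for m in cell_masks:
            union |= m
        if coloc_target_pcc is None:
            scale = cells[0].second_channel_scale if cells else 1.0
            ch2 = field_spec.bg_mean + scale * (signal - field_spec.bg_mean)
            ch2, c2 = _apply_optics_and_noise(field_spec, ch2, rng)
            clipped = clipped or c2
        else:
            rho = float(coloc_target_pcc)
            if not (-1.0 <= rho <= 1.0):
                raise ValueError("coloc_target_pcc must be in [-1, 1]")
            if not union.any():
                raise ValueError("coloc_target_pcc requires at least one cell")
            mu1 = ch1[union].mean()
            sd1 = ch1[union].std()
            if sd1 == 0:
                raise ValueError("channel 1 has zero variance over the cell mask")
            z1 = (ch1 - mu1) / sd1
            if abs(rho) == 1.0:
                mix = rho * z1
            else:
                z2 = rng.normal(size=z1.shape)
                z2 -= z2[union].mean()
                # Orthogonalize against z1 over the cell pixels, then
                # re-standardize there, so the sample PCC is exact.
                z2 -= (z2[union] @ z1[union] / (z1[union] @ z1[union])) * z1
                z2 /= z2[union].std()
                mix = rho * z1 + math.sqrt(1.0 - rho * rho) * z2
            scale = cells[0].second_channel_scale if cells else 1.0
            ch2 = field_spec.bg_mean + scale * sd1 * mix
            low = float(ch2.min())
            if low < 0:
                # A uniform shift is affine, so it preserves the calibrated
                # PCC exactly; clipping would distort it.
                ch2 -= low
        images.append(FieldImage(ch2, field_spec.pixel_size_um, channel="561"))

    manifest = GroundTruthManifest(
        field_spec,
        cells=list(cells),
        coloc_target_pcc=coloc_target_pcc,
        clipped_negative=clipped,
    )
    return images, manifest


def _nearest_pixel(spec: FieldSpec, center_um: tuple[float, float]) -> tuple[int, int]:
    col = int(np.clip(center_um[0] / spec.pixel_size_um, 0, spec.width_px - 1))
    row = int(np.clip(center_um[1] / spec.pixel_size_um, 0, spec.height_px - 1))
    return row, col


def render_frap_series(truth: FrapTruth, *, seed: int = 0) -> FrapTrace:
    """Simulate a bleach-and-recovery ROI trace.

    ``n_pre_frames`` frames at the pre-bleach level are followed by
    ``n_frames`` post-bleach frames sampled every ``frame_interval_s`` on the
    single-exponential recovery curve, with Gaussian noise of ``noise_sd`` on
    every frame. Post-bleach time starts at 0 (the first post-bleach frame is
    at the bleach instant).
    """
    rng = np.random.default_rng(seed)
    dt = truth.frame_interval_s
    t_pre = -dt * np.arange(truth.n_pre_frames, 0, -1)
    t_post = dt * np.arange(truth.n_frames)
    values = np.concatenate(
        [np.full(truth.n_pre_frames, truth.pre_bleach), truth.recovery(t_post)]
    )
    if truth.noise_sd > 0:
        values = values + rng.normal(0.0, truth.noise_sd, values.shape)
    return FrapTrace(
        times_s=np.concatenate([t_pre, t_post]),
        intensities=values,
        pre_bleach_frames=truth.n_pre_frames,
        roi_diameter_um=1.0,
    )


@dataclass
class KineticsTruth:
    """Per-frame ground truth for a nucleation-and-growth time series."""

    field_spec: FieldSpec
    times_s: list[float]
    frames: list[list[DropletSpec]]  # droplet state at each frame
    birth_times_s: list[float]
    plateau_diameter_um: list[float]
    plateau_partition_ratio: list[float]
    growth_tau_s: float
    generator_version: str = GENERATOR_VERSION


def render_kinetics_series(
    field_spec: FieldSpec,
    *,
    nucleation_rate: float,
    growth_tau_s: float,
    n_frames: int,
    frame_interval_s: float,
    nucleation_tau_s: float = 300.0,
    plateau_diameter_range: tuple[float, float] = (1.4, 1.8),
    plateau_partition_ratio: float = 7.7,
    min_render_diameter_um: float = 0.15,
) -> tuple[list[FieldImage], KineticsTruth]:
    """Simulate droplet nucleation and growth after a snap-cool.

    New droplets nucleate as a Poisson process whose rate decays with time
    constant ``nucleation_tau_s`` (so the count saturates); each droplet's
    diameter and partition ratio rise toward their plateaus as
    ``1 − exp(−Δt/growth_tau_s)``. Droplets smaller than
    ``min_render_diameter_um`` are recorded in the truth but not yet rendered.
    """
    if nucleation_rate < 0 or growth_tau_s <= 0 or frame_interval_s <= 0:
        raise ValueError("rates and time constants must be positive")
    rng = np.random.default_rng(field_spec.seed)
    margin = plateau_diameter_range[1] / 2 + 0.2
    times = [k * frame_interval_s for k in range(n_frames)]

    births: list[float] = []
    plat_d: list[float] = []
    plat_p: list[float] = []
    centers: list[tuple[float, float]] = []
    frames_img: list[FieldImage] = []
    frames_truth: list[list[DropletSpec]] = []

    for k, t in enumerate(times):
        lam = nucleation_rate * frame_interval_s * math.exp(-t / nucleation_tau_s)
        for _ in range(rng.poisson(lam) if lam > 0 else 0):
            births.append(t)
            plat_d.append(rng.uniform(*plateau_diameter_range))
            plat_p.append(plateau_partition_ratio)
            centers.append(
                (
                    rng.uniform(margin, field_spec.width_um - margin),
                    rng.uniform(margin, field_spec.height_um - margin),
                )
            )
        current: list[DropletSpec] = []
        for b, d_inf, p_inf, ctr in zip(births, plat_d, plat_p, centers):
            g = 1.0 - math.exp(-(t - b) / growth_tau_s) if t > b else 0.0
            d_now = d_inf * g
            p_now = 1.0 + (p_inf - 1.0) * g
            if d_now >= min_render_diameter_um:
                current.append(DropletSpec(ctr, d_now, max(p_now, 1.0)))
        frame_field = dataclasses.replace(field_spec, seed=field_spec.seed + 1 + k)
        img, _ = render_droplet_field(frame_field, current, allow_overlap=True)
        frames_img.append(img)
        frames_truth.append(current)

    truth = KineticsTruth(
        field_spec=field_spec,
        times_s=times,
        frames=frames_truth,
        birth_times_s=births,
        plateau_diameter_um=plat_d,
        plateau_partition_ratio=plat_p,
        growth_tau_s=growth_tau_s,
    )
    return frames_img, truth


# ---------------------------------------------------------------------------
# Population samplers


def sample_droplets(
    field_spec: FieldSpec,
    n: int,
    *,
    diameter_range: tuple[float, float] = (1.4, 1.8),
    partition_ratios: Sequence[float] = (7.7,),
    ring_fraction: float = 0.0,
    ring_core_fraction: float = 0.2,
    min_gap_um: float = 0.5,
    rng: np.random.Generator | None = None,
    max_attempts: int = 2000,
) -> list[DropletSpec]:
    """Draw ``n`` non-overlapping droplets uniformly over the field.

    Partition ratios cycle through ``partition_ratios``; a ``ring_fraction``
    of the droplets (chosen by the rng) are rendered as rings. Rejection
    sampling keeps surfaces at least ``min_gap_um`` apart.
    """
    rng = rng if rng is not None else np.random.default_rng(field_spec.seed)
    placed: list[DropletSpec] = []
    for i in range(n):
        d = rng.uniform(*diameter_range)
        r = d / 2
        for attempt in range(max_attempts):
            x = rng.uniform(r, field_spec.width_um - r)
            y = rng.uniform(r, field_spec.height_um - r)
            ok = all(
                math.hypot(x - p.center_um[0], y - p.center_um[1])
                >= r + p.radius_um + min_gap_um
                for p in placed
            )
            if ok:
                shape = "ring" if rng.random() < ring_fraction else "filled"
                placed.append(
                    DropletSpec(
                        (x, y),
                        d,
                        partition_ratios[i % len(partition_ratios)],
                        shape_class=shape,
                        ring_core_fraction=ring_core_fraction,
                    )
                )
                break
        else:
            raise RuntimeError(f"could not place droplet {i + 1}/{n}; field too crowded")
    return placed


def polar_foci(
    cell: CellSpec,
    n_foci: int,
    *,
    diameter_range: tuple[float, float] = (0.55, 0.7),
    partition_ratio: float = 4.0,
    rng: np.random.Generator | None = None,
    polar: bool = True,
) -> list[DropletSpec]:
    """Place ``n_foci`` foci on a cell's axis, poles first.

    Default placement mirrors the polar localization of bacterial RNA
    condensates: the first two foci sit within 15% of the pole-to-pole axis
    from each end, the third mid-cell, the fourth between pole and middle.
    With ``polar=False``, positions are drawn uniformly along the axis.
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    fracs = [0.15, 0.85, 0.5, 0.325]
    if n_foci > len(fracs):
        raise ValueError("at most 4 foci per cell are supported")
    foci = []
    for j in range(n_foci):
        frac = rng.uniform(0.1, 0.9) if not polar else fracs[j]
        d = rng.uniform(*diameter_range)
        foci.append(DropletSpec(cell.axis_point(frac), d, partition_ratio))
    return foci


def sample_rod_cells(
    field_spec: FieldSpec,
    n: int,
    *,
    length_range: tuple[float, float] = (3.0, 4.5),
    width_range: tuple[float, float] = (0.9, 1.1),
    cytoplasm_intensity: float = 200.0,
    foci_count_probs: Sequence[float] = (0.1, 0.45, 0.35, 0.1),
    focus_diameter_range: tuple[float, float] = (0.55, 0.7),
    focus_partition_ratio: float = 4.0,
    min_gap_um: float = 0.8,
    rng: np.random.Generator | None = None,
    max_attempts: int = 500,
    polar: bool = True,
) -> list[CellSpec]:
    """Draw ``n`` non-overlapping rods with 0–3 polar foci each.

    ``foci_count_probs`` gives P(0, 1, 2, ... foci); the default puts 80% of
    cells at 1–2 foci, the range bacterial CAG-repeat reporters occupy.
    Placement is rejection sampling on capsule-to-capsule distance with a
    ``min_gap_um`` clearance so neighboring cells never merge under blur.
    """
    rng = rng if rng is not None else np.random.default_rng(field_spec.seed)
    probs = np.asarray(foci_count_probs, float)
    probs = probs / probs.sum()
    cells: list[CellSpec] = []
    for i in range(n):
        L = rng.uniform(*length_range)
        W = rng.uniform(*width_range)
        half_span = L / 2 + 0.6  # keep the blur halo clear of the border
        for attempt in range(max_attempts):
            x = rng.uniform(half_span, field_spec.width_um - half_span)
            y = rng.uniform(half_span, field_spec.height_um - half_span)
            theta = rng.uniform(0, 180)
            cand = CellSpec((x, y), L, W, theta, cytoplasm_intensity)
            a0, a1 = cand.pole_points()
            ok = True
            for other in cells:
                b0, b1 = other.pole_points()
                dist = _segment_segment_distance(a0, a1, b0, b1)
                if dist < (W + other.width_um) / 2 + min_gap_um:
                    ok = False
                    break
            if ok:
                k = int(rng.choice(len(probs), p=probs))
                cand.foci = polar_foci(
                    cand,
                    k,
                    diameter_range=focus_diameter_range,
                    partition_ratio=focus_partition_ratio,
                    rng=rng,
                    polar=polar,
                )
                cells.append(cand)
                break
        else:
            raise RuntimeError(f"could not place cell {i + 1}/{n}; field too crowded")
    return cells
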