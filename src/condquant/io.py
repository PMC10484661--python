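"""TIFF input/output and tabular export.

Images are grayscale TIFF, 8- or 16-bit, single- or multi-page (pages are
channels or time frames, per caller). Pixel size comes from OME metadata
when present; an explicit override always wins, and a missing pixel size is
an error rather than a silent default — every downstream measurement is in
μm.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .cells import CellRecord, FocusRecord
from .image import FieldImage

__all__ = [
    "read_image",
    "read_stack",
    "write_image",
    "cells_to_frame",
    "foci_to_frame",
    "read_frap_csv",
]


def _ome_pixel_size(tif: tifffile.TiffFile) -> float | None:
    xml = tif.ome_metadata
    if not xml:
        return None
    m = re.search(r'PhysicalSizeX="([\d.eE+-]+)"', xml)
    return float(m.group(1)) if m else None


def _page_to_array(page) -> np.ndarray:
    arr = page.asarray()
    if arr.ndim == 3 or getattr(page, "samplesperpixel", 1) > 1:
        raise ValueError(
            "RGB/multi-sample TIFF pages are not supported; supply one grayscale channel per page"
        )
    return np.asarray(arr, dtype=float)


def read_stack(path, pixel_size_um: float | None = None) -> list[FieldImage]:
    """Read every page of a grayscale TIFF as a list of FieldImages, in order."""
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        px = pixel_size_um if pixel_size_um is not None else _ome_pixel_size(tif)
        if px is None:
            raise ValueError(
                f"{path}: no pixel size in OME metadata and no override given; "
                "pass pixel_size_um explicitly"
            )
        return [
            FieldImage(_page_to_array(page), px, meta={"source": str(path), "page": i})
            for i, page in enumerate(tif.pages)
        ]


def read_image(path, pixel_size_um: float | None = None) -> FieldImage:
    """Read a single-page grayscale TIFF (first page of a stack)."""
    return read_stack(path, pixel_size_um)[0]


def write_image(image: FieldImage, path) -> None:
    """Write a FieldImage as a 16-bit grayscale OME-TIFF with pixel size."""
    data = np.clip(np.rint(image.data), 0, 65535).astype(np.uint16)
    tifffile.imwrite(
        path,
        data,
        photometric="minisblack",
        metadata={
            "axes": "YX",
            "PhysicalSizeX": image.pixel_size_um,
            "PhysicalSizeXUnit": "µm",
            "PhysicalSizeY": image.pixel_size_um,
            "PhysicalSizeYUnit": "µm",
        },
        ome=True,
    )


def cells_to_frame(cells: list[CellRecord]) -> pd.DataFrame:
    cols = [
        "label",
        "area_um2",
        "length_um",
        "width_um",
        "aspect_ratio",
        "solidity",
        "mean_intensity",
        "cellular_bg_mean",
        "is_single_rod",
        "foci_count",
        "centroid_x_um",
        "centroid_y_um",
    ]
    rows = [
        (
            c.label,
            c.area_um2,
            c.length_um,
            c.width_um,
            c.aspect_ratio,
            c.solidity,
            c.mean_intensity,
            c.cellular_bg_mean,
            c.is_single_rod,
            c.foci_count,
            c.centroid_um[0],
            c.centroid_um[1],
        )
        for c in cells
    ]
    return pd.DataFrame(rows, columns=cols)


def foci_to_frame(foci: list[FocusRecord]) -> pd.DataFrame:
    cols = [
        "label",
        "parent_cell",
        "area_um2",
        "equivalent_diameter_um",
        "mean_intensity",
        "peak_intensity",
        "partition_ratio",
        "centroid_x_um",
        "centroid_y_um",
    ]
    rows = [
        (
            f.label,
            f.parent_cell,
            f.area_um2,
            f.equivalent_diameter_um,
            f.mean_intensity,
            f.peak_intensity,
            f.partition_ratio,
            f.centroid_um[0],
            f.centroid_um[1],
        )
        for f in foci
    ]
    return pd.DataFrame(rows, columns=cols)


def read_frap_csv(path, pre_bleach_frames: int = 1):
    """Read a (time_s, intensity) CSV into a FrapTrace."""
    from .frap import FrapTrace

    df = pd.read_csv(path)
    cols = {c.lower().strip(): c for c in df.columns}
    tcol = cols.get("time_s") or cols.get("time") or df.columns[0]
    icol = cols.get("intensity") or df.columns[1]
    return FrapTrace(
        df[tcol].to_numpy(float), df[icol].to_numpy(float), pre_bleach_frames
    )
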