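"""Two-channel colocalization via Pearson's correlation coefficient.

PCC over a pixel mask is the standard colocalization readout for dual
reporters (e.g. a Broccoli/DFHBI-1T condensate channel against a
Pepper/HBC620 target-RNA channel). It is invariant under independent affine
rescaling of either channel, so acquisition gain and offset do not matter.
The mask should restrict the computation to cell pixels: including the empty
background correlates the two channels through shared emptiness and inflates
the coefficient.
"""

from __future__ import annotations

import numpy as np

from .cells import CellRecord
from .image import FieldImage

__all__ = ["pearson_colocalization", "cells_union_mask"]


def cells_union_mask(cells: list[CellRecord], shape: tuple[int, int]) -> np.ndarray:
    """Union of detected cell masks — the default colocalization mask."""
    out = np.zeros(shape, dtype=bool)
    for c in cells:
        out |= c.full_mask(shape)
    return out


def pearson_colocalization(
    ch1: FieldImage, ch2: FieldImage, mask: np.ndarray | None = None
) -> float:
    """Pearson correlation of two channels over a pixel mask.

    ``mask=None`` uses every pixel (whole-image option); normally pass the
    union of detected cell masks. Raises if either channel has zero variance
    over the mask.
    """
    if ch1.shape != ch2.shape:
        raise ValueError("channels must have the same shape")
    if mask is None:
        a, b = ch1.data.ravel(), ch2.data.ravel()
    else:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != ch1.shape:
            raise ValueError("mask shape must match the images")
        if not mask.any():
            raise ValueError("mask is empty")
        a, b = ch1.data[mask], ch2.data[mask]
    if a.std() == 0 or b.std() == 0:
        raise ValueError("zero variance in a channel over the mask; PCC undefined")
    return float(np.corrcoef(a, b)[0, 1])
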