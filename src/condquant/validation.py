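"""Matching detected objects to ground-truth manifests.

Used to validate the pipeline against the synthetic generator: detections
and truth objects are paired greedily by centroid distance, and precision /
recall follow from the pairing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

__all__ = ["MatchResult", "match_by_centroid", "precision_recall"]


@dataclass
class MatchResult:
    pairs: list[tuple[int, int]]  # (truth index, detection index)
    unmatched_truth: list[int]
    unmatched_detections: list[int]

    @property
    def n_true_positive(self) -> int:
        return len(self.pairs)

    @property
    def precision(self) -> float:
        n_det = len(self.pairs) + len(self.unmatched_detections)
        return self.n_true_positive / n_det if n_det else float("nan")

    @property
    def recall(self) -> float:
        n_truth = len(self.pairs) + len(self.unmatched_truth)
        return self.n_true_positive / n_truth if n_truth else float("nan")


def match_by_centroid(
    truth_centers: Sequence[tuple[float, float]],
    detected_centers: Sequence[tuple[float, float]],
    max_dist_um: float = 0.5,
) -> MatchResult:
    """Greedy one-to-one pairing by increasing centroid distance."""
    candidates = []
    for i, (tx, ty) in enumerate(truth_centers):
        for j, (dx, dy) in enumerate(detected_centers):
            d = math.hypot(tx - dx, ty - dy)
            if d <= max_dist_um:
                candidates.append((d, i, j))
    candidates.sort()
    used_t: set[int] = set()
    used_d: set[int] = set()
    pairs = []
    for _d, i, j in candidates:
        if i in used_t or j in used_d:
            continue
        pairs.append((i, j))
        used_t.add(i)
        used_d.add(j)
    return MatchResult(
        pairs=pairs,
        unmatched_truth=[i for i in range(len(truth_centers)) if i not in used_t],
        unmatched_detections=[j for j in range(len(detected_centers)) if j not in used_d],
    )


def precision_recall(
    truth_centers: Sequence[tuple[float, float]],
    detected_centers: Sequence[tuple[float, float]],
    max_dist_um: float = 0.5,
) -> tuple[float, float]:
    m = match_by_centroid(truth_centers, detected_centers, max_dist_um)
    return m.precision, m.recall
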