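"""Group comparisons, kinetics summarization and aggregation utilities.

Covers the statistics behind the summary figures: the two-tailed pooled-
variance Student's t-test used for every pairwise comparison, the t90
summarization of condensation kinetics (time to 90% of plateau), grouping of
per-condensate measurements by the repeat-content ratio N_CAG/N_total, and
the linear fluorescence-to-concentration calibration.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "ConstructMetadata",
    "KineticsSummary",
    "two_sample_ttest",
    "kinetics_summary",
    "t90_time",
    "aggregate_by_ratio",
    "fluorescence_to_concentration",
]

logger = logging.getLogger(__name__)


@dataclass
class ConstructMetadata:
    """A tagged RNA construct: CAG-repeat count and total length.

    ``ratio_percent`` is the repeat content N_CAG/N_total expressed in %,
    computed as (3 × repeat count) / total nucleotides by default — i.e. the
    repeat *nucleotides* over the transcript length. Set
    ``count_convention="repeats"`` to use the raw repeat count instead.
    """

    name: str
    n_cag_repeats: int
    total_length_nt: int
    count_convention: str = "nucleotides"

    def __post_init__(self) -> None:
        if not (self.total_length_nt >= 3 * self.n_cag_repeats >= 0):
            raise ValueError("require total_length_nt >= 3*n_cag_repeats >= 0")
        if self.count_convention not in ("nucleotides", "repeats"):
            raise ValueError("count_convention must be 'nucleotides' or 'repeats'")

    @property
    def ratio_percent(self) -> float:
        num = 3 * self.n_cag_repeats if self.count_convention == "nucleotides" else self.n_cag_repeats
        return 100.0 * num / self.total_length_nt


def two_sample_ttest(a, b, *, welch: bool = False) -> tuple[float, float]:
    """Two-tailed two-sample t-test; pooled variance (Student) by default.

    Returns ``(t, p)``. With equal pooled variance of zero: identical means
    give p = 1 (no evidence of a difference is the only sensible answer for
    two identical constants), different means raise (the statistic is
    undefined). ``welch=True`` switches to the unequal-variance form.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = a.size, b.size
    if na < 2 or nb < 2:
        raise ValueError("each sample needs at least 2 observations")
    if welch:
        t, p = sps.ttest_ind(a, b, equal_var=False)
        return float(t), float(p)
    ma, mb = a.mean(), b.mean()
    va = a.var(ddof=1)
    vb = b.var(ddof=1)
    df = na + nb - 2
    pooled = ((na - 1) * va + (nb - 1) * vb) / df
    if pooled == 0:
        if ma == mb:
            return 0.0, 1.0
        raise ValueError("zero pooled variance with unequal means: t undefined")
    t = (ma - mb) / math.sqrt(pooled * (1.0 / na + 1.0 / nb))
    p = 2.0 * sps.t.sf(abs(t), df)
    return float(t), float(p)


@dataclass
class KineticsSummary:
    """Plateaus and times-to-90% for count, diameter and partition ratio."""

    t90_count_s: float
    t90_diameter_s: float
    t90_partition_s: float
    plateau_count: float
    plateau_diameter_um: float
    plateau_partition_ratio: float


def t90_time(times_s, values, *, plateau_fraction: float = 0.1) -> tuple[float, float]:
    """Time at which a rising series first reaches 90% of its plateau.

    The plateau is the mean of the final ``plateau_fraction`` of frames
    (at least one). The 90% level is measured from the first-frame baseline,
    ``baseline + 0.9 × (plateau − baseline)``, which makes t90 invariant
    under affine rescaling of the values; for series rising from zero this
    coincides with crossing 0.9 × plateau. Crossings are located by linear
    interpolation between frames. Returns ``(t90, plateau)``; t90 is NaN
    when the series never reaches the level.
    """
    t = np.asarray(times_s, dtype=float)
    y = np.asarray(values, dtype=float)
    if t.size < 2 or t.size != y.size:
        raise ValueError("need matching time/value series of length >= 2")
    n_tail = max(int(round(plateau_fraction * t.size)), 1)
    plateau = float(y[-n_tail:].mean())
    baseline = float(y[0])
    level = baseline + 0.9 * (plateau - baseline)
    if plateau == baseline:
        return float(t[0]), plateau
    for i in range(t.size):
        if y[i] >= level:
            if i == 0:
                return float(t[0]), plateau
            # interpolate between the bracketing frames
            f = (level - y[i - 1]) / (y[i] - y[i - 1])
            return float(t[i - 1] + f * (t[i] - t[i - 1])), plateau
    return float("nan"), plateau


def kinetics_summary(per_frame: pd.DataFrame) -> KineticsSummary:
    """Summarize a condensation time series.

    ``per_frame`` needs columns ``time_s``, ``count``, ``mean_diameter_um``
    and ``mean_partition_ratio`` (one row per frame, ≥ 5 frames). Each series
    is reduced to its plateau and t90 via :func:`t90_time`.
    """
    if len(per_frame) < 5:
        raise ValueError("need at least 5 frames")
    t = per_frame["time_s"].to_numpy()
    t90c, pc = t90_time(t, per_frame["count"].to_numpy())
    t90d, pdm = t90_time(t, per_frame["mean_diameter_um"].to_numpy())
    t90p, pp = t90_time(t, per_frame["mean_partition_ratio"].to_numpy())
    return KineticsSummary(
        t90_count_s=t90c,
        t90_diameter_s=t90d,
        t90_partition_s=t90p,
        plateau_count=pc,
        plateau_diameter_um=pdm,
        plateau_partition_ratio=pp,
    )


def aggregate_by_ratio(
    records: pd.DataFrame,
    constructs: dict[str, ConstructMetadata],
    *,
    construct_column: str = "construct",
    value_columns: tuple[str, ...] = ("radius_um", "partition_ratio"),
) -> pd.DataFrame:
    """Per-construct means and SEMs keyed by N_CAG/N_total (in %).

    ``records`` holds one row per condensate with a construct name column;
    SEM is over condensates within each construct group. Output rows are
    sorted by ratio, so the table is invariant to record order.
    """
    if records.empty:
        raise ValueError("need at least one record group")
    rows = []
    for name, group in records.groupby(construct_column):
        meta = constructs[name]
        row = {"construct": name, "ratio_percent": meta.ratio_percent, "n": len(group)}
        for col in value_columns:
            vals = group[col].to_numpy(dtype=float)
            row[f"mean_{col}"] = float(vals.mean())
            row[f"sem_{col}"] = float(vals.std(ddof=1) / math.sqrt(len(vals))) if len(vals) > 1 else float("nan")
        rows.append(row)
    return pd.DataFrame(rows).sort_values(["ratio_percent", "construct"]).reset_index(drop=True)


def fluorescence_to_concentration(
    mean_intensity: float, calibration: tuple[float, float]
) -> float:
    """Linear intensity → concentration map: (I − intercept) / slope, in μM.

    The calibration (slope in ADU/μM, intercept in ADU) comes from the
    user's known-concentration standards. Negative results are clipped to 0
    with a warning.
    """
    slope, intercept = calibration
    if not (slope > 0):
        raise ValueError("calibration slope must be positive")
    conc = (mean_intensity - intercept) / slope
    if conc < 0:
        logger.warning("intensity %.3g below calibration intercept; clipping to 0 uM", mean_intensity)
        return 0.0
    return float(conc)
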