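"""FRAP trace normalization and single-exponential recovery fitting.

A fluorescence-recovery-after-photobleaching experiment bleaches a ~1 μm
region and follows the ROI mean intensity, typically every 5 s for a few
minutes. The recovery extent and speed report molecular mobility: liquid-like
condensates recover most of their signal within tens of seconds, gel-like
ones barely recover over minutes.

The model fitted here is a single exponential,

    I(t) = A − B·exp(−t/τ),

on the post-bleach frames (t measured from the bleach). From the fit,
``plateau = A``, ``post_bleach = A − B`` (the model value at t = 0),

    mobile_fraction = (plateau − post_bleach) / (pre_bleach − post_bleach),
    t_half = τ·ln 2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

__all__ = ["FrapTrace", "FrapFit", "frap_normalize", "frap_fit"]

#: Mobile fractions above 1 by more than this margin are flagged: small
#: overshoot is expected from noise, larger overshoot means a bad trace.
MOBILE_FRACTION_CEILING = 1.05


@dataclass
class FrapTrace:
    """Time-stamped ROI intensities with a pre-bleach baseline.

    The first ``pre_bleach_frames`` samples are pre-bleach; the remaining
    samples follow the bleach, with the first post-bleach frame at the bleach
    instant. Times must be strictly increasing.
    """

    times_s: np.ndarray
    intensities: np.ndarray
    pre_bleach_frames: int = 1
    roi_diameter_um: float = 1.0

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.times_s.shape != self.intensities.shape or self.times_s.ndim != 1:
            raise ValueError("times_s and intensities must be 1D arrays of equal length")
        if np.any(np.diff(self.times_s) <= 0):
            raise ValueError("times_s must be strictly increasing")
        if not (1 <= self.pre_bleach_frames < len(self.times_s)):
            raise ValueError("need at least one pre-bleach and one post-bleach frame")

    @property
    def pre_bleach_mean(self) -> float:
        return float(self.intensities[: self.pre_bleach_frames].mean())

    @property
    def post_times(self) -> np.ndarray:
        t = self.times_s[self.pre_bleach_frames :]
        return t - t[0]

    @property
    def post_intensities(self) -> np.ndarray:
        return self.intensities[self.pre_bleach_frames :]


@dataclass
class FrapFit:
    """Result of a single-exponential recovery fit."""

    mobile_fraction: float
    t_half_s: float
    tau_s: float
    plateau: float
    post_bleach: float
    pre_bleach: float
    residual_rms: float
    flags: list = field(default_factory=list)


def frap_normalize(trace: FrapTrace, *, full_scale: bool = False) -> FrapTrace:
    """Rescale a trace so the pre-bleach mean is 1.

    With ``full_scale=True``, the first post-bleach value is additionally
    subtracted before rescaling, mapping the trace to [0, 1] between the
    bleach floor and the pre-bleach level (double normalization).
    """
    pre = trace.pre_bleach_mean
    if pre <= 0:
        raise ValueError("pre-bleach mean must be positive to normalize")
    if full_scale:
        floor = float(trace.post_intensities[0])
        span = pre - floor
        if span <= 0:
            raise ValueError("post-bleach floor is not below the pre-bleach mean")
        values = (trace.intensities - floor) / span
    else:
        values = trace.intensities / pre
    return FrapTrace(
        trace.times_s.copy(), values, trace.pre_bleach_frames, trace.roi_diameter_um
    )


def frap_fit(trace: FrapTrace) -> FrapFit:
    """Fit I(t) = A − B·exp(−t/τ) to the post-bleach frames.

    The trace should be normalized (pre-bleach mean 1); the fit itself only
    uses the post-bleach frames and the trace's pre-bleach mean. Initial
    guesses: post-bleach floor from the first post-bleach frame, plateau from
    the mean of the last three frames, τ from the time to half range.
    """
    t = trace.post_times
    y = trace.post_intensities
    if len(t) < 5:
        raise ValueError("need at least 5 post-bleach frames to fit")
    pre = trace.pre_bleach_mean

    post0 = float(y[0])
    plateau0 = float(y[-3:].mean())
    half_level = post0 + 0.5 * (plateau0 - post0)
    above = np.nonzero(y >= half_level)[0] if plateau0 > post0 else np.array([], int)
    tau0 = float(t[above[0]] / np.log(2)) if above.size and t[above[0]] > 0 else float(
        max(t[-1] / 5.0, np.diff(t).min())
    )
    p0 = (plateau0, max(plateau0 - post0, 1e-6), tau0)

    def model(tt, A, B, tau):
        return A - B * np.exp(-tt / tau)

    try:
        popt, _ = curve_fit(
            model,
            t,
            y,
            p0=p0,
            bounds=((-np.inf, 0.0, 1e-9), (np.inf, np.inf, np.inf)),
            maxfev=10000,
        )
    except (RuntimeError, ValueError) as exc:  # non-convergence
        raise RuntimeError(
            f"FRAP fit did not converge (initial guess A={p0[0]:.4g}, "
            f"B={p0[1]:.4g}, tau={p0[2]:.4g} s): {exc}"
        ) from exc
    A, B, tau = (float(v) for v in popt)
    post = A - B
    denom = pre - post
    mobile = (A - post) / denom if denom > 0 else 0.0
    flags = []
    if mobile < 0:
        flags.append("negative_mobile_fraction")
        mobile = 0.0
    if mobile > MOBILE_FRACTION_CEILING:
        flags.append("mobile_fraction_above_ceiling")
    resid = y - model(t, *popt)
    return FrapFit(
        mobile_fraction=mobile,
        t_half_s=tau * float(np.log(2)),
        tau_s=tau,
        plateau=A,
        post_bleach=post,
        pre_bleach=pre,
        residual_rms=float(np.sqrt(np.mean(resid**2))),
        flags=flags,
    )
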