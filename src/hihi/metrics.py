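"""Quality and physics metrics: tSNR, CNR, Ernst angle, steady-state ratio."""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .simulate import SignalModel, steady_state_baseline

__all__ = [
    "EpochWindows",
    "tsnr",
    "cnr",
    "ernst_angle",
    "steady_state_ratio",
    "default_windows",
]


@dataclass(frozen=True)
class EpochWindows:
    """Baseline and response pseudo-volume index ranges (half-open)."""

    baseline_window: tuple[int, int]
    response_window: tuple[int, int]

    def __post_init__(self) -> None:
        b0, b1 = self.baseline_window
        r0, r1 = self.response_window
        if not (0 <= b0 < b1 and 0 <= r0 < r1):
            raise ValueError("windows must be non-empty, non-negative ranges")
        if max(b0, r0) < min(b1, r1):
            raise ValueError("baseline and response windows overlap")


def default_windows(timecourse: np.ndarray, width: int = 10) -> EpochWindows:
    """Baseline = first `width` pseudo volumes (pre-response), response =
    `width` volumes centered on the empirical peak of the time course."""
    x = np.asarray(timecourse, dtype=np.float64)
    peak = int(np.nanargmax(x))
    half = width // 2
    r0 = max(width, peak - half)  # never overlap the baseline window
    r1 = min(x.size, r0 + width)
    return EpochWindows(baseline_window=(0, width), response_window=(r0, r1))


def tsnr(timecourse: np.ndarray) -> float:
    """Temporal SNR: temporal mean / temporal standard deviation.

    Missing (NaN) samples are excluded.  Raises on fewer than 2 finite
    samples or zero variance (a constant series has undefined tSNR).
    """
    x = np.asarray(timecourse, dtype=np.float64)
    x = x[np.isfinite(x)]
    if x.size < 2:
        raise ValueError("tsnr needs at least 2 finite samples")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("tsnr undefined for a constant series")
    return float(x.mean() / sd)


def cnr(timecourse: np.ndarray, windows: EpochWindows) -> float:
    """Contrast-to-noise: (response mean − baseline mean) / baseline SD."""
    x = np.asarray(timecourse, dtype=np.float64)
    b0, b1 = windows.baseline_window
    r0, r1 = windows.response_window
    if b1 > x.size or r1 > x.size:
        raise ValueError("windows exceed series length")
    base = x[b0:b1][np.isfinite(x[b0:b1])]
    resp = x[r0:r1][np.isfinite(x[r0:r1])]
    if base.size < 2 or resp.size < 1:
        raise ValueError("degenerate windows (too few finite samples)")
    sd = base.std(ddof=1)
    if sd == 0:
        raise ValueError("baseline has zero variance")
    return float((resp.mean() - base.mean()) / sd)


def ernst_angle(tr: float, t1: float) -> float:
    """Optimal spoiled steady-state flip angle, degrees: arccos(exp(−TR/T1)).

    `tr` and `t1` in the same unit (seconds or ms).  25° for TR = 0.1 s and
    T1 = 1 s; approaches 90° as TR ≫ T1.
    """
    if tr <= 0 or t1 <= 0:
        raise ValueError("tr and t1 must be > 0")
    return math.degrees(math.acos(math.exp(-tr / t1)))


def steady_state_ratio(tr_a: float, tr_b: float, t1: float) -> float:
    """Ratio of Ernst-angle steady-state signals at two repetition times.

    Both arms use their own optimal flip angle; `tr_a`, `tr_b`, `t1` in
    seconds.  Quantifies the signal cost of fast sampling: a TR of 0.1 s
    retains only about one fourth of the steady-state signal of a 2-s TR
    for T1 = 1 s.
    """
    if tr_a <= 0 or tr_b <= 0 or t1 <= 0:
        raise ValueError("all arguments must be > 0")

    def s(tr: float) -> float:
        model = SignalModel(t1=t1, flip_angle=ernst_angle(tr, t1),
                            baseline_m0=1.0)
        return steady_state_baseline(model, tr * 1000.0)

    return s(tr_a) / s(tr_b)
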