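"""Signal conditioning around the reshuffle.

Slow scanner drift is removed from the *original* series by a voxel-wise
polynomial fit (second order by default) before reshuffling; after
reshuffling, task repeats are averaged slot-wise to raise temporal SNR.
A simple NaN-aware moving average is provided for display smoothing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .reshuffle import EpiTimeSeries, HihiTimeSeries

__all__ = [
    "DetrendSpec",
    "detrend_polynomial",
    "average_repeats",
    "moving_average",
]


@dataclass(frozen=True)
class DetrendSpec:
    """Polynomial detrend settings.

    keep_mean=True adds the voxel temporal mean back after removing the
    fitted polynomial, so mean-based quantities (tSNR) stay meaningful.
    """

    polynomial_order: int = 2
    keep_mean: bool = True

    def __post_init__(self) -> None:
        if self.polynomial_order < 0:
            raise ValueError("polynomial_order must be >= 0")


def detrend_polynomial(
    series: EpiTimeSeries, spec: DetrendSpec = DetrendSpec()
) -> EpiTimeSeries:
    """Subtract a voxel-wise least-squares polynomial over volume index.

    The fit is over the volume index (each voxel's samples are equally
    spaced in time, so any polynomial drift in acquisition time is a
    polynomial in volume index of the same order).  Residuals are
    orthogonal to the polynomial basis; applying the operation twice is a
    no-op.
    """
    n_vol = series.n_volumes
    if n_vol <= spec.polynomial_order:
        raise ValueError(
            f"need more than {spec.polynomial_order} volumes to fit an "
            f"order-{spec.polynomial_order} polynomial, got {n_vol}"
        )
    t = np.arange(n_vol, dtype=np.float64)
    basis = np.polynomial.polynomial.polyvander(t, spec.polynomial_order)
    flat = series.data.reshape(-1, n_vol).T  # (n_vol, n_voxels)
    coef, *_ = np.linalg.lstsq(basis, flat, rcond=None)
    resid = flat - basis @ coef
    if spec.keep_mean:
        resid += flat.mean(axis=0, keepdims=True)
    return EpiTimeSeries(
        data=resid.T.reshape(series.data.shape), geometry=series.geometry
    )


def average_repeats(repeats: list[HihiTimeSeries]) -> HihiTimeSeries:
    """Slot-wise mean over task repeats.

    A slot contributes to the mean wherever its repeat filled it
    (``fill_count > 0``); the output ``fill_count`` is the number of
    contributing repeats, so disjoint partial coverages merge into their
    union.  Averaging R repeats with independent noise divides the slot
    noise standard deviation by sqrt(R).
    """
    if not repeats:
        raise ValueError("need at least one repeat")
    first = repeats[0]
    for r in repeats[1:]:
        if r.data.shape != first.data.shape:
            raise ValueError(
                f"shape mismatch: {r.data.shape} vs {first.data.shape}"
            )
        if r.pseudo_volume_tr != first.pseudo_volume_tr:
            raise ValueError("pseudo_volume_tr differs between repeats")
    filled = np.stack([r.fill_count > 0 for r in repeats])  # (R, sl, pv)
    data = np.stack([r.data for r in repeats])  # (R, x, y, sl, pv)
    data = np.where(filled[:, None, None], data, 0.0)
    n = filled.sum(axis=0)  # (sl, pv)
    with np.errstate(invalid="ignore"):
        mean = data.sum(axis=0) / n[None, None]
    mean[..., n == 0] = np.nan
    return HihiTimeSeries(
        data=mean,
        pseudo_volume_tr=first.pseudo_volume_tr,
        fill_count=n,
        geometry=first.geometry,
    )


def moving_average(timecourse: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average with shrinking edges, skipping NaNs.

    `window` must be odd.  At the series edges the window shrinks to the
    available samples; missing (NaN) samples are excluded from each local
    mean (a position whose window holds no finite sample stays NaN).
    """
    x = np.asarray(timecourse, dtype=np.float64)
    if x.ndim != 1:
        raise ValueError("timecourse must be 1D")
    if window < 1 or window % 2 == 0:
        raise ValueError(f"window must be odd and >= 1, got {window}")
    if window > x.size:
        raise ValueError(f"window {window} exceeds series length {x.size}")
    good = np.isfinite(x)
    vals = np.where(good, x, 0.0)
    kernel = np.ones(window)
    sums = np.convolve(vals, kernel, mode="same")
    counts = np.convolve(good.astype(np.float64), kernel, mode="same")
    with np.errstate(invalid="ignore"):
        out = sums / counts
    out[counts == 0] = np.nan
    return out
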