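"""Slice-wise EPI acquisition simulator with known ground truth.

Generates synthetic long-TR multislice runs of a HiHi paradigm: every voxel
of slice ``s`` in volume ``v`` is sampled at the excitation instant of that
slice, ``(v * n_slices + acq_index(s)) * slice_tr``, and carries a spoiled
steady-state baseline modulated by a hemodynamic response to each task
event, plus polynomial drift and i.i.d. Gaussian noise.  The true epoch
time course on the pseudo-series grid is returned alongside, so the whole
schedule -> acquire -> detrend -> reshuffle pipeline can be checked for
exact recovery (noise-free) or SNR behaviour (noisy).

The hemodynamic response is a difference of two gamma densities (peak at
~5 s, undershoot at ~15 s, conventional defaults) with an optional early
negative "initial dip" term; amplitudes are in percent signal change.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .reshuffle import EpiTimeSeries
from .scheduler import (
    AcquisitionGeometry,
    ParadigmDesign,
    StimulusSchedule,
    total_volumes,
)

__all__ = [
    "HrfModel",
    "NoiseSpec",
    "SignalModel",
    "GroundTruth",
    "hrf_value",
    "steady_state_baseline",
    "calibrate_noise",
    "generate_run",
]

_NORM_GRID_DT = 0.005  # s; grid for locating the positive peak


@dataclass(frozen=True)
class HrfModel:
    """Parametric hemodynamic response: double gamma plus initial dip.

    ``peak_delay``/``undershoot_delay`` are the gamma means (s),
    ``*_dispersion`` their scale parameters (s); ``undershoot_ratio`` scales
    the undershoot lobe.  ``dip_amplitude`` (fraction of the positive peak)
    subtracts a short-latency gamma bump peaking near ``dip_delay`` to mimic
    the transient early deoxygenation seen in some visual responses.
    ``response_amplitude`` is the positive peak height in percent signal
    change; the response is identically zero beyond ``support_s``.
    """

    peak_delay: float = 6.0
    undershoot_delay: float = 16.0
    peak_dispersion: float = 1.0
    undershoot_dispersion: float = 1.0
    undershoot_ratio: float = 1.0 / 6.0
    dip_amplitude: float = 0.0
    dip_delay: float = 1.0
    dip_dispersion: float = 0.25
    response_amplitude: float = 2.0
    support_s: float = 32.0

    def __post_init__(self) -> None:
        if self.peak_delay <= 0 or self.undershoot_delay <= 0:
            raise ValueError("gamma delays must be > 0")
        if self.peak_dispersion <= 0 or self.undershoot_dispersion <= 0:
            raise ValueError("dispersions must be > 0")
        if self.dip_amplitude < 0:
            raise ValueError("dip_amplitude must be >= 0")
        if self.dip_delay <= 0 or self.dip_dispersion <= 0:
            raise ValueError("dip delay/dispersion must be > 0")
        if self.support_s <= 0:
            raise ValueError("support_s must be > 0")

    def _shape(self, t: np.ndarray) -> np.ndarray:
        """Unscaled response; zero at t=0 and beyond the support."""
        g = stats.gamma.pdf(t, a=self.peak_delay / self.peak_dispersion,
                            scale=self.peak_dispersion)
        u = stats.gamma.pdf(
            t, a=self.undershoot_delay / self.undershoot_dispersion,
            scale=self.undershoot_dispersion)
        core = g - self.undershoot_ratio * u
        out = core / self._core_peak()
        if self.dip_amplitude > 0:
            d = stats.gamma.pdf(t, a=self.dip_delay / self.dip_dispersion,
                                scale=self.dip_dispersion)
            d_peak = stats.gamma.pdf(
                (self.dip_delay / self.dip_dispersion - 1) * self.dip_dispersion,
                a=self.dip_delay / self.dip_dispersion,
                scale=self.dip_dispersion)
            out = out - self.dip_amplitude * d / d_peak
        out = np.where(t > self.support_s, 0.0, out)
        return out

    def _core_peak(self) -> float:
        grid = np.arange(0.0, self.support_s + _NORM_GRID_DT, _NORM_GRID_DT)
        g = stats.gamma.pdf(grid, a=self.peak_delay / self.peak_dispersion,
                            scale=self.peak_dispersion)
        u = stats.gamma.pdf(
            grid, a=self.undershoot_delay / self.undershoot_dispersion,
            scale=self.undershoot_dispersion)
        return float((g - self.undershoot_ratio * u).max())

    def __call__(self, t) -> np.ndarray:
        return hrf_value(t, self)


@dataclass(frozen=True)
class NoiseSpec:
    """Additive noise: i.i.d. Gaussian sigma plus polynomial drift.

    ``drift_coefficients`` are (c0, c1, c2): drift(t) = c0 + c1 t + c2 t^2
    with t in seconds, in signal units — quadratic so an order-2 detrend
    removes it exactly.
    """

    sigma: float = 0.0
    drift_coefficients: tuple[float, ...] = (0.0, 0.0, 0.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if len(self.drift_coefficients) > 3:
            raise ValueError("drift is at most quadratic (3 coefficients)")


@dataclass(frozen=True)
class SignalModel:
    """Spoiled steady-state signal parameters (T1 in s, flip in degrees)."""

    t1: float = 1.0
    flip_angle: float = 73.0
    baseline_m0: float = 1000.0

    def __post_init__(self) -> None:
        if self.t1 <= 0:
            raise ValueError("t1 must be > 0")
        if not 0 < self.flip_angle <= 90:
            raise ValueError("flip_angle must be in (0, 90] degrees")


@dataclass(frozen=True)
class GroundTruth:
    """True single-event epoch time course on the pseudo-series grid."""

    times_s: np.ndarray        # (n_pseudo_volumes,), 0, slice_tr, 2*slice_tr...
    response_percent: np.ndarray  # hrf at those times, percent signal change
    baseline: float            # steady-state baseline signal

    @property
    def expected_signal(self) -> np.ndarray:
        """Noise- and drift-free reshuffled value at each pseudo time."""
        return self.baseline * (1.0 + self.response_percent / 100.0)


def hrf_value(t, model: HrfModel) -> np.ndarray | float:
    """Hemodynamic response at time(s) `t` (s), percent signal change.

    Scaled so the positive peak equals ``model.response_amplitude``;
    ``hrf(0) == 0``.  Raises on negative times (the response is causal).
    """
    arr = np.asarray(t, dtype=np.float64)
    if (arr < 0).any():
        raise ValueError("hrf is causal: t must be >= 0")
    shape = model._shape(arr)
    grid = np.arange(0.0, model.support_s + _NORM_GRID_DT, _NORM_GRID_DT)
    pos_peak = model._shape(grid).max()
    out = model.response_amplitude * shape / pos_peak
    return float(out) if np.isscalar(t) else out


def steady_state_baseline(model: SignalModel, volume_tr: float) -> float:
    """Spoiled gradient-echo steady-state signal for repetition time `volume_tr` (ms).

    S = M0 · sin(α) · (1 − E1) / (1 − cos(α)·E1),  E1 = exp(−TR/T1).
    Long TR at 90° recovers the full M0; short TR leaves little
    longitudinal relaxation and much less signal even at the optimal angle.
    """
    e1 = math.exp(-(volume_tr / 1000.0) / model.t1)
    a = math.radians(model.flip_angle)
    return model.baseline_m0 * math.sin(a) * (1 - e1) / (1 - math.cos(a) * e1)


def calibrate_noise(target_tsnr: float, baseline: float) -> float:
    """Gaussian sigma that gives a constant-signal run the target tSNR."""
    if target_tsnr <= 0:
        raise ValueError("target_tsnr must be > 0")
    return baseline / target_tsnr


def _drift(t_s: np.ndarray, coeffs: tuple[float, ...]) -> np.ndarray:
    out = np.zeros_like(t_s)
    for p, c in enumerate(coeffs):
        out += c * t_s**p
    return out


def generate_run(
    geometry: AcquisitionGeometry,
    design: ParadigmDesign,
    schedule: StimulusSchedule,
    hrf: HrfModel = HrfModel(),
    noise: NoiseSpec = NoiseSpec(),
    signal: SignalModel = SignalModel(),
    shape_xy: tuple[int, int] = (8, 8),
) -> tuple[EpiTimeSeries, StimulusSchedule, GroundTruth]:
    """Simulate one slice-wise-acquired EPI run of a HiHi paradigm.

    Every voxel of slice ``s`` (anatomical position) in volume ``v`` is
    sampled at ``(v * n_slices + acq_index(s)) * slice_tr``; its value is

        baseline · (1 + Σ_task_events hrf(t − t_event)/100) + drift(t) + ε,

    ε ~ N(0, sigma²) i.i.d. per voxel and time point, reproducible from
    ``noise.seed``.  All voxels of one slice share the excitation instant.
    Control (non-task) events evoke no response.

    Returns the series, the schedule (unchanged), and the ground-truth
    single-event epoch time course on the pseudo grid.
    """
    n_sl = geometry.n_slices
    n_vol = total_volumes(design, geometry, full_coverage=False)
    last_needed = max(
        (e.global_slice_index for e in schedule), default=-1
    ) + design.n_epoch_volumes * n_sl
    if last_needed > n_vol * n_sl:
        raise ValueError(
            f"schedule needs {last_needed} slices, run has {n_vol * n_sl}"
        )
    str_s = geometry.slice_tr / 1000.0
    baseline = steady_state_baseline(signal, geometry.volume_tr)

    # per-(slice, volume) sampling times; identical for all voxels of a slice
    acq_index = np.argsort(np.asarray(geometry.slice_order))  # position -> order
    t = (np.arange(n_vol)[None, :] * n_sl + acq_index[:, None]) * str_s  # (sl, vol)

    resp = np.zeros_like(t)
    for e in schedule:
        if not e.is_task:
            continue
        dt = t - e.global_slice_index * str_s
        live = (dt >= 0) & (dt <= hrf.support_s)
        if live.any():
            resp[live] += hrf_value(dt[live], hrf)
    clean = baseline * (1.0 + resp / 100.0) + _drift(t, noise.drift_coefficients)

    nx, ny = shape_xy
    data = np.broadcast_to(clean, (nx, ny, n_sl, n_vol)).copy()
    if noise.sigma > 0:
        rng = np.random.default_rng(noise.seed)
        data += rng.normal(0.0, noise.sigma, size=data.shape)

    n_pv = design.n_epoch_volumes * n_sl
    times = np.arange(n_pv) * str_s
    truth = GroundTruth(
        times_s=times,
        response_percent=hrf_value(times, hrf),
        baseline=baseline,
    )
    return EpiTimeSeries(data=data, geometry=geometry), schedule, truth
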