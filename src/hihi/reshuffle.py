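"""The HiHi reshuffling operator.

Slices of a long-TR EPI run are redistributed into a *pseudo time series*
ordered by post-stimulus (epoch) time: pseudo volume ``i`` collects only
slices that were excited exactly ``i * slice_tr`` after their stimulus, so
the pseudo series samples the BOLD response at the slice TR (100 ms for a
20-slice, 2-s-TR run) while every slice keeps its anatomical position.
Because all slices of a pseudo volume share one post-stimulus time, the
reordering doubles as an exact slice-time correction — no interpolation.

Empty slots (possible with jittered measured onsets) are marked NaN with
``fill_count`` 0; slots hit by several events hold the mean of their
sources, with the multiplicity recorded in ``fill_count``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .scheduler import AcquisitionGeometry, StimulusSchedule

__all__ = [
    "EpiTimeSeries",
    "HihiTimeSeries",
    "SliceMapping",
    "CoverageReport",
    "build_mapping",
    "apply_reshuffle",
    "invert_reshuffle",
    "validate_coverage",
]


@dataclass
class EpiTimeSeries:
    """A 4D EPI run: ``data[x, y, slice, volume]`` plus its geometry."""

    data: np.ndarray
    geometry: AcquisitionGeometry

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 4:
            raise ValueError(f"data must be 4D, got shape {self.data.shape}")
        if self.data.shape[2] != self.geometry.n_slices:
            raise ValueError(
                f"axis 2 has {self.data.shape[2]} slices, geometry says "
                f"{self.geometry.n_slices}"
            )

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]


@dataclass
class HihiTimeSeries:
    """Pseudo time series: ``data[x, y, slice, pseudo_volume]``.

    ``pseudo_volume_tr`` equals the slice TR of the source run.
    ``fill_count[slice, pseudo_volume]`` records how many source slices were
    averaged into each slot; 0 means the slot is missing (NaN data).
    """

    data: np.ndarray
    pseudo_volume_tr: float
    fill_count: np.ndarray
    geometry: AcquisitionGeometry

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.fill_count = np.asarray(self.fill_count, dtype=np.int64)
        if self.data.ndim != 4:
            raise ValueError(f"data must be 4D, got shape {self.data.shape}")
        if self.fill_count.shape != self.data.shape[2:]:
            raise ValueError(
                f"fill_count shape {self.fill_count.shape} does not match "
                f"(n_slices, n_pseudo_volumes) = {self.data.shape[2:]}"
            )

    @property
    def n_pseudo_volumes(self) -> int:
        return self.data.shape[3]


@dataclass(frozen=True)
class SliceMapping:
    """Bijective record set (orig volume, slice) -> (pseudo volume, slice).

    Column arrays, one entry per transferred slice: ``event`` (index into
    the schedule), ``orig_volume``, ``slice_pos`` (anatomical position,
    preserved by the transfer), ``pseudo_volume``.
    """

    event: np.ndarray
    orig_volume: np.ndarray
    slice_pos: np.ndarray
    pseudo_volume: np.ndarray
    n_slices: int
    n_pseudo_volumes: int

    def __len__(self) -> int:
        return len(self.event)


@dataclass(frozen=True)
class CoverageReport:
    """Per-slot fill counts of a mapping plus empty/multiple summaries."""

    fill_count: np.ndarray  # (n_slices, n_pseudo_volumes)
    n_empty: int
    n_multiple: int

    @property
    def complete(self) -> bool:
        return self.n_empty == 0 and self.n_multiple == 0


def build_mapping(
    schedule: StimulusSchedule,
    geometry: AcquisitionGeometry,
    n_epoch_volumes: int,
    n_run_volumes: int | None = None,
    task_only: bool = False,
    blocks: set[int] | None = None,
) -> SliceMapping:
    """Map each event's epoch slices onto the pseudo-series slot grid.

    For event ``j`` starting at global slice ``q_j``, the slice excited at
    global index ``q_j + i`` (for ``i`` in ``[0, n_epoch_volumes*n_slices)``)
    lands in pseudo volume ``i`` at its own anatomical position: the i-th
    pseudo volume holds only slices acquired exactly ``i * slice_tr`` after
    their stimulus.

    Parameters
    ----------
    n_run_volumes:
        Length of the acquired run, for overrun checking.  If given, an
        epoch extending past the run raises.
    task_only, blocks:
        Optional filters: keep only task events, or only events of the
        given block numbers (used to reshuffle one block at a time).

    Warns if two epochs overlap (their slots will be averaged).
    """
    n_sl = geometry.n_slices
    epoch_slices = n_epoch_volumes * n_sl
    events = [
        (j, e)
        for j, e in enumerate(schedule)
        if (not task_only or e.is_task)
        and (blocks is None or e.block in blocks)
    ]
    ev_idx, ov, sp, pv = [], [], [], []
    prev_end = -1
    overlap = False
    for j, e in events:
        q = e.global_slice_index
        if n_run_volumes is not None and q + epoch_slices > n_run_volumes * n_sl:
            raise ValueError(
                f"epoch of event {j} (slices {q}..{q + epoch_slices - 1}) "
                f"overruns the {n_run_volumes}-volume run"
            )
        if q <= prev_end:
            overlap = True
        prev_end = max(prev_end, q + epoch_slices - 1)
        k = q + np.arange(epoch_slices)
        ev_idx.append(np.full(epoch_slices, j))
        ov.append(k // n_sl)
        sp.append(np.asarray(geometry.slice_order)[k % n_sl])
        pv.append(np.arange(epoch_slices))
    if overlap:
        warnings.warn(
            "event epochs overlap; shared slots will be averaged",
            stacklevel=2,
        )
    cat = (lambda a: np.concatenate(a) if a else np.empty(0, dtype=np.int64))
    return SliceMapping(
        event=cat(ev_idx),
        orig_volume=cat(ov),
        slice_pos=cat(sp),
        pseudo_volume=cat(pv),
        n_slices=n_sl,
        n_pseudo_volumes=epoch_slices,
    )


def apply_reshuffle(series: EpiTimeSeries, mapping: SliceMapping) -> HihiTimeSeries:
    """Redistribute the slices of `series` according to `mapping`.

    Each target slot receives the arithmetic mean of all source slices
    mapped to it; slots nothing maps to are NaN.  With a canonical
    (gap-free, one-slice-shift) schedule every slot is filled exactly once
    and the transfer is a pure copy.
    """
    if mapping.n_slices != series.geometry.n_slices:
        raise ValueError(
            f"mapping built for {mapping.n_slices} slices, series has "
            f"{series.geometry.n_slices}"
        )
    if len(mapping) and mapping.orig_volume.max() >= series.n_volumes:
        raise ValueError(
            f"mapping references volume {mapping.orig_volume.max()}, run has "
            f"only {series.n_volumes}"
        )
    nx, ny, n_sl, _ = series.data.shape
    n_pv = mapping.n_pseudo_volumes
    acc = np.zeros((n_sl, n_pv, nx, ny))
    counts = np.zeros((n_sl, n_pv), dtype=np.int64)
    if len(mapping):
        # (record, x, y) source slices, accumulated onto (slice, pseudo) slots
        src = series.data[:, :, mapping.slice_pos, mapping.orig_volume]
        np.add.at(acc, (mapping.slice_pos, mapping.pseudo_volume),
                  np.moveaxis(src, 2, 0))
        np.add.at(counts, (mapping.slice_pos, mapping.pseudo_volume), 1)
    with np.errstate(invalid="ignore"):
        out = acc / counts[:, :, None, None]
    out[counts == 0] = np.nan
    return HihiTimeSeries(
        data=np.moveaxis(out, (0, 1), (2, 3)),
        pseudo_volume_tr=series.geometry.slice_tr,
        fill_count=counts,
        geometry=series.geometry,
    )


def invert_reshuffle(
    hihi: HihiTimeSeries, mapping: SliceMapping, n_volumes: int
) -> EpiTimeSeries:
    """Restore a (partial) original series from a pseudo series.

    Only defined when no slot was averaged (``fill_count <= 1``); mapped
    source slices are restored bit-exactly, unmapped ones are NaN.
    """
    if (hihi.fill_count > 1).any():
        raise ValueError(
            "cannot invert: some slots averaged several source slices "
            f"(max fill_count {hihi.fill_count.max()})"
        )
    nx, ny = hihi.data.shape[:2]
    n_sl = mapping.n_slices
    out = np.full((nx, ny, n_sl, n_volumes), np.nan)
    out[:, :, mapping.slice_pos, mapping.orig_volume] = (
        hihi.data[:, :, mapping.slice_pos, mapping.pseudo_volume]
    )
    return EpiTimeSeries(data=out, geometry=hihi.geometry)


def validate_coverage(
    mapping: SliceMapping,
    geometry: AcquisitionGeometry,
    n_epoch_volumes: int,
) -> CoverageReport:
    """Count how often each (slice, pseudo volume) slot is filled.

    A canonical schedule with one stimulus per slice yields
    ``n_empty == n_multiple == 0``: after n_slices stimuli all slices in
    all pseudo volumes are populated exactly once.
    """
    n_sl = geometry.n_slices
    n_pv = n_epoch_volumes * n_sl
    counts = np.zeros((n_sl, n_pv), dtype=np.int64)
    if len(mapping):
        np.add.at(counts, (mapping.slice_pos, mapping.pseudo_volume), 1)
    return CoverageReport(
        fill_count=counts,
        n_empty=int((counts == 0).sum()),
        n_multiple=int((counts > 1).sum()),
    )
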