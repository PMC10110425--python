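"""Paradigm scheduling on the slice-time grid.

A HiHi experiment acquires a long-TR multislice EPI run while presenting a
sparse event-related task whose onsets are locked to individual slice
excitations.  Each successive stimulus is shifted by one slice relative to
the volume raster, so that after ``n_slices`` stimuli every post-stimulus
slice time has been sampled once.  This module computes the slice-time grid,
the volume budget of such a paradigm, and the canonical stimulus schedule;
it also snaps measured response times (e.g. grip onsets) onto the grid.

All internal indices are 0-based; onsets are in milliseconds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

__all__ = [
    "AcquisitionGeometry",
    "ParadigmDesign",
    "StimulusEvent",
    "StimulusSchedule",
    "slice_tr",
    "volumes_per_block",
    "total_volumes",
    "build_schedule",
    "snap_onset",
]


@dataclass(frozen=True)
class AcquisitionGeometry:
    """Slice count, volume TR and slice acquisition order of one EPI run.

    Parameters
    ----------
    n_slices:
        Number of 2D slices per EPI volume.
    volume_tr:
        Volume repetition time in milliseconds.
    slice_order:
        Permutation mapping acquisition index -> anatomical slice position.
        Default is ascending (slice_order[k] = k), i.e. the k-th excited
        slice of each volume sits at slab position k.
    """

    n_slices: int
    volume_tr: float
    slice_order: tuple[int, ...] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.n_slices < 1:
            raise ValueError(f"n_slices must be >= 1, got {self.n_slices}")
        if self.volume_tr <= 0:
            raise ValueError(f"volume_tr must be > 0, got {self.volume_tr}")
        order = self.slice_order
        if order is None:
            order = tuple(range(self.n_slices))
        else:
            order = tuple(int(k) for k in order)
            if sorted(order) != list(range(self.n_slices)):
                raise ValueError(
                    "slice_order must be a permutation of 0..n_slices-1"
                )
        object.__setattr__(self, "slice_order", order)

    @property
    def slice_tr(self) -> float:
        """Time between successive slice excitations, ms."""
        return self.volume_tr / self.n_slices

    def acquisition_index(self, slice_pos: int) -> int:
        """Within-volume excitation index of the slice at `slice_pos`."""
        return self.slice_order.index(slice_pos)


@dataclass(frozen=True)
class ParadigmDesign:
    """Event counts and volume budget of a HiHi block paradigm.

    A block presents ``n_stimuli_per_block`` stimuli, each followed by
    ``n_epoch_volumes`` EPI volumes of post-stimulus data, with the onset
    shifted by one slice per stimulus.  Full coverage of the pseudo series
    requires one stimulus per slice.
    """

    n_stimuli_per_block: int
    n_epoch_volumes: int
    n_blocks: int = 1
    task_block_flags: tuple[bool, ...] = field(default=None)  # type: ignore[assignment]
    n_dummy_start: int = 0
    n_dummy_end: int = 0

    def __post_init__(self) -> None:
        for name in ("n_stimuli_per_block", "n_epoch_volumes", "n_blocks",
                     "n_dummy_start", "n_dummy_end"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        flags = self.task_block_flags
        if flags is None:
            flags = tuple(True for _ in range(self.n_blocks))
        else:
            flags = tuple(bool(f) for f in flags)
            if len(flags) != self.n_blocks:
                raise ValueError(
                    f"task_block_flags has length {len(flags)}, "
                    f"expected n_blocks={self.n_blocks}"
                )
        object.__setattr__(self, "task_block_flags", flags)

    @property
    def n_task_blocks(self) -> int:
        return sum(self.task_block_flags)


@dataclass(frozen=True)
class StimulusEvent:
    """One stimulus (or motor response) on the global slice-time grid."""

    global_slice_index: int
    onset_ms: float
    block: int
    is_task: bool


@dataclass(frozen=True)
class StimulusSchedule:
    """Ordered stimulus events of one run, on the slice-time grid."""

    events: tuple[StimulusEvent, ...]

    def __post_init__(self) -> None:
        idx = [e.global_slice_index for e in self.events]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError("global_slice_index must be strictly increasing")

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self):
        return iter(self.events)

    @property
    def n_task_events(self) -> int:
        return sum(e.is_task for e in self.events)

    def task_events(self) -> tuple[StimulusEvent, ...]:
        return tuple(e for e in self.events if e.is_task)


def slice_tr(geometry: AcquisitionGeometry) -> float:
    """Slice repetition time in ms: volume TR divided by slice count.

    After reshuffling this becomes the volume TR of the pseudo time series
    (100 ms for the canonical 20-slice, 2-s-TR acquisition).
    """
    return geometry.slice_tr


def volumes_per_block(
    design: ParadigmDesign,
    geometry: AcquisitionGeometry,
    full_coverage: bool = True,
) -> int:
    """Original EPI volumes consumed by one block.

    One stimulus needs ``n_epoch_volumes`` volumes of post-stimulus data;
    shifting the onset by one slice per stimulus accumulates one extra
    volume over a full-coverage block, hence
    ``n_stimuli_per_block * n_epoch_volumes + 1`` (201 for the canonical
    20-stimulus, 10-volume design).  In general a block of N stimuli spans
    ``N * (n_epoch_volumes * n_slices + 1)`` slices, rounded up to whole
    volumes; the two formulas coincide when N == n_slices.

    Raises
    ------
    ValueError
        If ``full_coverage`` (the default) and
        ``n_stimuli_per_block != n_slices`` — the block then cannot fill
        every slot of the pseudo series.
    """
    if design.n_stimuli_per_block != geometry.n_slices:
        if full_coverage:
            raise ValueError(
                f"full coverage needs n_stimuli_per_block == n_slices "
                f"({design.n_stimuli_per_block} != {geometry.n_slices}); "
                "the pseudo time series would have empty slots"
            )
        step = design.n_epoch_volumes * geometry.n_slices + 1
        return -(-design.n_stimuli_per_block * step // geometry.n_slices)
    return design.n_stimuli_per_block * design.n_epoch_volumes + 1


def total_volumes(
    design: ParadigmDesign,
    geometry: AcquisitionGeometry,
    full_coverage: bool = True,
) -> int:
    """Original EPI volumes of the whole run, dummies included."""
    return (
        design.n_blocks * volumes_per_block(design, geometry, full_coverage)
        + design.n_dummy_start
        + design.n_dummy_end
    )


def build_schedule(
    design: ParadigmDesign,
    geometry: AcquisitionGeometry,
    start_slice_index: int | None = None,
) -> StimulusSchedule:
    """Canonical slice-shifted stimulus schedule for a HiHi run.

    Event ``j`` (counted across all blocks) fires at global slice index
    ``q_j = q_0 + j * (n_epoch_volumes * n_slices + 1)``: each epoch spans
    ``n_epoch_volumes * n_slices`` slices and the next onset is shifted one
    further slice.  Because the step is ≡ 1 (mod n_slices), consecutive
    stimuli within a block walk through all slice phases; with one stimulus
    per slice each block occupies exactly ``volumes_per_block`` volumes and
    every block repeats the same internal structure.

    Parameters
    ----------
    start_slice_index:
        Global slice index of the first stimulus.  Defaults to the first
        slice after the leading dummy volumes.  Must not fall inside the
        dummies.

    Raises
    ------
    ValueError
        If the start lies inside the leading dummies, or if any epoch would
        overrun into the trailing dummies / past the end of the run.
    """
    n_sl = geometry.n_slices
    epoch_slices = design.n_epoch_volumes * n_sl
    step = epoch_slices + 1
    q0 = (design.n_dummy_start * n_sl
          if start_slice_index is None else int(start_slice_index))
    if q0 < design.n_dummy_start * n_sl:
        raise ValueError(
            f"first stimulus at slice {q0} falls inside the "
            f"{design.n_dummy_start} leading dummy volumes"
        )
    n_events = design.n_blocks * design.n_stimuli_per_block
    n_total = total_volumes(design, geometry, full_coverage=False)
    last_epoch_slice = q0 + (n_events - 1) * step + epoch_slices - 1
    limit = (n_total - design.n_dummy_end) * n_sl
    if n_events and last_epoch_slice >= limit:
        raise ValueError(
            f"schedule overruns the run: last epoch slice {last_epoch_slice} "
            f">= usable limit {limit} ({n_total} volumes, "
            f"{design.n_dummy_end} trailing dummies)"
        )
    str_ms = geometry.slice_tr
    events = []
    for j in range(n_events):
        block = j // design.n_stimuli_per_block if design.n_stimuli_per_block else 0
        q = q0 + j * step
        events.append(
            StimulusEvent(
                global_slice_index=q,
                onset_ms=q * str_ms,
                block=block,
                is_task=design.task_block_flags[block],
            )
        )
    return StimulusSchedule(events=tuple(events))


def snap_onset(
    measured_onset_ms: float,
    geometry: AcquisitionGeometry,
    mode: Literal["nearest", "floor"] = "nearest",
) -> int:
    """Snap a measured onset onto the slice-excitation grid.

    Motor responses are detected with millisecond timing (grip signal) but
    the reshuffle needs the index of the slice being excited at response
    time.  ``nearest`` picks the slice whose excitation is closest
    (quantization error <= slice_tr / 2, ties toward the earlier slice);
    ``floor`` picks the slice currently being acquired.
    """
    if measured_onset_ms < 0:
        raise ValueError(f"onset must be >= 0, got {measured_onset_ms}")
    x = measured_onset_ms / geometry.slice_tr
    if mode == "floor":
        return int(math.floor(x))
    if mode != "nearest":
        raise ValueError(f"unknown snap mode {mode!r}")
    k = math.floor(x)
    return int(k + 1) if (x - k) > 0.5 else int(k)


def schedule_from_onsets(
    onsets_ms: Sequence[float],
    blocks: Sequence[int],
    is_task: Sequence[bool],
    geometry: AcquisitionGeometry,
    mode: Literal["nearest", "floor"] = "nearest",
) -> StimulusSchedule:
    """Build a (possibly jittered) schedule from measured onset times."""
    if not (len(onsets_ms) == len(blocks) == len(is_task)):
        raise ValueError("onsets, blocks and is_task must have equal length")
    str_ms = geometry.slice_tr
    events = []
    for onset, block, task in zip(onsets_ms, blocks, is_task):
        q = snap_onset(onset, geometry, mode=mode)
        events.append(
            StimulusEvent(
                global_slice_index=q,
                onset_ms=q * str_ms,
                block=int(block),
                is_task=bool(task),
            )
        )
    return StimulusSchedule(events=tuple(events))
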