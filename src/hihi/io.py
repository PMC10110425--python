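"""Readers and writers: NIfTI-1 series, BIDS-dialect events.tsv, mapping TSV,
YAML run configuration.

Events files follow the BIDS events dialect — tab-separated with `onset`
(seconds, 3 decimals), `duration` (seconds), `trial_type`
(`visual` | `motor` | `control`) and `block` (integer).  Internally all
timing is in milliseconds on the slice grid; conversion is exact at 3
decimals for the canonical 100-ms slice TR.

NIfTI conventions: time on the 4th axis, repetition time in pixdim[4]
(seconds); slices ordered inferior→superior along axis 3; voxel indices
0-based.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .reshuffle import EpiTimeSeries, HihiTimeSeries, SliceMapping
from .scheduler import (
    AcquisitionGeometry,
    ParadigmDesign,
    StimulusSchedule,
    schedule_from_onsets,
)
from .simulate import HrfModel, NoiseSpec, SignalModel

__all__ = [
    "RunConfig",
    "read_epi",
    "write_epi",
    "read_hihi",
    "write_hihi",
    "read_events",
    "write_events",
    "write_mapping",
    "read_config",
]

EVENT_COLUMNS = ("onset", "duration", "trial_type", "block")


def read_epi(path: str | Path, volume_tr_ms: float | None = None) -> EpiTimeSeries:
    """Load a 4D NIfTI-1 run; volume TR from pixdim[4] unless overridden."""
    img = nib.load(str(path))
    if img.ndim != 4:
        raise ValueError(f"{path}: expected a 4D image, got {img.ndim}D")
    if volume_tr_ms is None:
        tr_s = float(img.header.get_zooms()[3])
        if tr_s <= 0:
            raise ValueError(
                f"{path}: nonpositive TR {tr_s} in header; pass volume_tr_ms"
            )
        # pixdim is float32; round to microseconds
        volume_tr_ms = round(tr_s * 1000.0, 3)
    data = np.asarray(img.dataobj, dtype=np.float64)
    geometry = AcquisitionGeometry(
        n_slices=data.shape[2], volume_tr=volume_tr_ms
    )
    return EpiTimeSeries(data=data, geometry=geometry)


def write_epi(series: EpiTimeSeries, path: str | Path) -> None:
    """Write a run as NIfTI-1 with the volume TR in pixdim[4] (seconds)."""
    img = nib.Nifti1Image(series.data, affine=np.eye(4))
    zooms = list(img.header.get_zooms())
    zooms[3] = series.geometry.volume_tr / 1000.0
    img.header.set_zooms(zooms)
    img.header.set_xyzt_units(xyz="mm", t="sec")
    nib.save(img, str(path))


def write_hihi(hihi: HihiTimeSeries, path: str | Path,
               fill_count_path: str | Path | None = None) -> None:
    """Write a pseudo series; pixdim[4] carries the pseudo volume TR.

    The per-slot fill counts can be written alongside as TSV.
    """
    img = nib.Nifti1Image(hihi.data, affine=np.eye(4))
    zooms = list(img.header.get_zooms())
    zooms[3] = hihi.pseudo_volume_tr / 1000.0
    img.header.set_zooms(zooms)
    img.header.set_xyzt_units(xyz="mm", t="sec")
    nib.save(img, str(path))
    if fill_count_path is not None:
        pd.DataFrame(hihi.fill_count).to_csv(
            fill_count_path, sep="\t", header=False, index=False
        )


def read_hihi(path: str | Path, geometry: AcquisitionGeometry,
              fill_count_path: str | Path | None = None) -> HihiTimeSeries:
    """Load a pseudo series written by :func:`write_hihi`."""
    img = nib.load(str(path))
    if img.ndim != 4:
        raise ValueError(f"{path}: expected a 4D image, got {img.ndim}D")
    data = np.asarray(img.dataobj, dtype=np.float64)
    tr_ms = round(float(img.header.get_zooms()[3]) * 1000.0, 3)
    if fill_count_path is not None:
        fill = pd.read_csv(fill_count_path, sep="\t", header=None).to_numpy()
    else:
        fill = (~np.isnan(data)).all(axis=(0, 1)).astype(np.int64)
    return HihiTimeSeries(
        data=data, pseudo_volume_tr=tr_ms, fill_count=fill, geometry=geometry
    )


def write_events(schedule: StimulusSchedule, path: str | Path,
                 task_type: str = "visual",
                 stimulus_duration_s: float = 0.375) -> None:
    """Write a schedule as a BIDS-dialect events.tsv (onsets in seconds)."""
    rows = [
        {
            "onset": round(e.onset_ms / 1000.0, 3),
            "duration": stimulus_duration_s,
            "trial_type": task_type if e.is_task else "control",
            "block": e.block,
        }
        for e in schedule
    ]
    pd.DataFrame(rows, columns=list(EVENT_COLUMNS)).to_csv(
        path, sep="\t", index=False, float_format="%.3f"
    )


def read_events(path: str | Path, geometry: AcquisitionGeometry,
                mode: Literal["nearest", "floor"] = "nearest") -> StimulusSchedule:
    """Read an events.tsv and snap onsets onto the slice-time grid.

    Rows with trial_type ``control`` become non-task events (they mark the
    nominal schedule of the no-task control block); everything else is a
    task event.
    """
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing events columns {missing}")
    if len(df) == 0:
        return StimulusSchedule(events=())
    if (df["onset"] < 0).any():
        raise ValueError(f"{path}: negative onsets")
    return schedule_from_onsets(
        onsets_ms=(df["onset"] * 1000.0).to_numpy(),
        blocks=df["block"].to_numpy(),
        is_task=(df["trial_type"] != "control").to_numpy(),
        geometry=geometry,
        mode=mode,
    )


def write_mapping(mapping: SliceMapping, path: str | Path) -> None:
    """Export a slice mapping as TSV (event, orig_volume, slice, pseudo_volume)."""
    pd.DataFrame(
        {
            "event": mapping.event,
            "orig_volume": mapping.orig_volume,
            "slice": mapping.slice_pos,
            "pseudo_volume": mapping.pseudo_volume,
        }
    ).to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class RunConfig:
    """Full simulation configuration (geometry, paradigm, HRF, noise, signal)."""

    geometry: AcquisitionGeometry
    design: ParadigmDesign
    hrf: HrfModel
    noise: NoiseSpec
    signal: SignalModel
    shape_xy: tuple[int, int] = (8, 8)
    seed: int = 0


def read_config(path: str | Path) -> RunConfig:
    """Load a YAML simulation config.

    Recognised top-level keys: ``geometry``, ``design``, ``hrf``, ``noise``,
    ``signal``, ``shape_xy``, ``seed``; each section holds the keyword
    arguments of the corresponding model (unknown keys raise).
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    seed = int(raw.get("seed", 0))
    noise_kwargs = dict(raw.get("noise", {}))
    noise_kwargs.setdefault("seed", seed)
    if "drift_coefficients" in noise_kwargs:
        noise_kwargs["drift_coefficients"] = tuple(
            noise_kwargs["drift_coefficients"]
        )
    geo_kwargs = dict(raw.get("geometry", {}))
    if "slice_order" in geo_kwargs and geo_kwargs["slice_order"] is not None:
        geo_kwargs["slice_order"] = tuple(geo_kwargs["slice_order"])
    design_kwargs = dict(raw.get("design", {}))
    if "task_block_flags" in design_kwargs and design_kwargs["task_block_flags"] is not None:
        design_kwargs["task_block_flags"] = tuple(design_kwargs["task_block_flags"])
    return RunConfig(
        geometry=AcquisitionGeometry(**geo_kwargs),
        design=ParadigmDesign(**design_kwargs),
        hrf=HrfModel(**raw.get("hrf", {})),
        noise=NoiseSpec(**noise_kwargs),
        signal=SignalModel(**raw.get("signal", {})),
        shape_xy=tuple(raw.get("shape_xy", (8, 8))),
        seed=seed,
    )
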