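"""Volume budget and stimulus schedule of the canonical HiHi paradigm.

20 slices at a 2-s volume TR give a 100-ms slice TR.  Each of the 20
stimuli per block is followed by 10 EPI volumes and shifted by one slice,
so one block needs 20*10 + 1 = 201 volumes; 5 blocks (4 task + 1 control)
plus 5 dummy volumes at each end give the full run length.
"""

from hihi import (
    AcquisitionGeometry,
    ParadigmDesign,
    build_schedule,
    slice_tr,
    total_volumes,
    volumes_per_block,
)

geometry = AcquisitionGeometry(n_slices=20, volume_tr=2000.0)
design = ParadigmDesign(
    n_stimuli_per_block=20,
    n_epoch_volumes=10,
    n_blocks=5,
    task_block_flags=(True, True, True, True, False),
    n_dummy_start=5,
    n_dummy_end=5,
)

print(f"slice TR:            {slice_tr(geometry):g} ms")
print(f"volumes per block:   {volumes_per_block(design, geometry)}")
print(f"total volumes:       {total_volumes(design, geometry)}")

schedule = build_schedule(design, geometry)
print(f"events:              {len(schedule)} ({schedule.n_task_events} task)")
first, second = schedule.events[:2]
print(f"first two onsets:    {first.onset_ms / 1000:.1f} s "
      f"(slice {first.global_slice_index % 20 + 1} of volume "
      f"{first.global_slice_index // 20 + 1}), "
      f"{second.onset_ms / 1000:.1f} s "
      f"(slice {second.global_slice_index % 20 + 1} of volume "
      f"{second.global_slice_index // 20 + 1})")
print("-> each stimulus fires one slice later in the volume raster, one")
print("   10-volume epoch after the previous one.")
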