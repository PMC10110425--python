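"""End-to-end: simulate a noise-free run, reshuffle it, recover the HRF.

A slice-wise acquisition of the canonical paradigm samples each voxel's
hemodynamic response at 2-s intervals, but at stimulus-locked offsets that
differ by 100 ms between events.  Reshuffling the slices by post-stimulus
time yields a 200-point, 100-ms-resolution epoch that matches the true
response to numerical precision when no noise is present.
"""

import numpy as np

from hihi import (
    AcquisitionGeometry,
    HrfModel,
    NoiseSpec,
    ParadigmDesign,
    apply_reshuffle,
    build_mapping,
    build_schedule,
    generate_run,
    validate_coverage,
)

geometry = AcquisitionGeometry(n_slices=20, volume_tr=2000.0)
design = ParadigmDesign(
    n_stimuli_per_block=20, n_epoch_volumes=10, n_blocks=1,
    task_block_flags=(True,), n_dummy_start=5, n_dummy_end=5,
)
schedule = build_schedule(design, geometry)

# visual-style response with an initial dip, support within the 20.1-s
# inter-stimulus interval so epochs do not overlap
hrf = HrfModel(dip_amplitude=0.1, response_amplitude=2.0, support_s=20.0)
series, schedule, truth = generate_run(
    geometry, design, schedule, hrf=hrf, noise=NoiseSpec(sigma=0.0),
    shape_xy=(4, 4),
)
print(f"simulated run:       {series.n_volumes} volumes of "
      f"{geometry.n_slices} slices (TR {geometry.volume_tr:g} ms)")

mapping = build_mapping(schedule, geometry, 10, n_run_volumes=series.n_volumes)
coverage = validate_coverage(mapping, geometry, 10)
print(f"coverage:            {coverage.n_empty} empty, "
      f"{coverage.n_multiple} averaged slots (complete={coverage.complete})")

hihi_series = apply_reshuffle(series, mapping)
print(f"pseudo time series:  {hihi_series.n_pseudo_volumes} volumes at "
      f"{hihi_series.pseudo_volume_tr:g} ms")

recovered = hihi_series.data[0, 0, 0, :]
err = np.max(np.abs(recovered - truth.expected_signal)
             / truth.expected_signal)
peak = np.argmax(truth.response_percent)
print(f"true peak:           +{truth.response_percent[peak]:.2f}% at "
      f"{truth.times_s[peak]:.1f} s post stimulus")
print(f"max relative error of the recovered epoch: {err:.2e}")
print("-> the reshuffled series reproduces the 100-ms-sampled response "
      "exactly.")
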