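# Methods

## The reshuffling model

An EPI run acquires `S` slices per volume at volume repetition time `T`
(ms), so slice excitations are `T/S` apart (the slice TR). Acquisition
order is a permutation `slice_order` mapping excitation index to anatomical
slab position (default ascending). Global slice index `k` (0-based, over
the whole run) denotes the excitation at time `k · T/S`; it lives in volume
`k div S` at acquisition position `k mod S`.

A stimulus scheduled at global slice `q` defines an epoch of
`E · S` slices (`E` = post-stimulus volumes). The mapping sends the slice
at `k = q + i` to pseudo volume `i` at its own anatomical position, for
`i ∈ [0, E·S)`. Consequences, all exact by construction:

- the pseudo series has `E·S` volumes at TR = `T/S`;
- every slice of pseudo volume `i` was excited exactly `i · T/S` after its
  stimulus — the reordering *is* the slice-time correction, with no
  interpolation;
- samples of one voxel from adjacent original volumes within an epoch land
  `S` pseudo volumes apart (20 for the canonical geometry), which is why
  the noise correlation structure of the pseudo series differs from an
  ordinary time series.

### Canonical schedules

Stimulus `j` (counted across blocks) fires at `q_j = q_0 + j·(E·S + 1)`:
each onset is one epoch plus one slice after the previous, i.e. shifted by
one slice phase (the step is ≡ 1 mod S). With one stimulus per slice
(`N = S` per block) the `S` epochs of a block tile the `(slice, pseudo
volume)` grid bijectively, and a block occupies exactly `N·E + 1` volumes —
the `+1` being the volume accumulated by the `S` one-slice shifts. Chaining
the step uniformly across block boundaries makes every block an exact
201-volume copy of the first (for the 20×10 design), which is what makes
`total volumes = n_blocks · (N·E + 1) + dummies` hold. One spare slice
separates the last epoch of a block from the first stimulus of the next.

By default the first stimulus sits at the first slice after the leading
dummy volumes. Start offsets of more than one slice are supported but then
the final epoch no longer fits the canonical volume budget; `build_schedule`
raises rather than let an epoch extend into the trailing dummies.

### Degenerate slots

Measured (jittered) onsets can map two epochs onto the same slot or leave
slots empty. Policy: slots hold the arithmetic mean of all their sources,
with the multiplicity in `fill_count`; empty slots are NaN with
`fill_count = 0`, never interpolated or silently zeroed. Inversion
(`invert_reshuffle`) is defined only when no slot was averaged; it restores
every mapped source slice bit-exactly and NaN-marks the rest.

### Onset snapping

Measured response times (e.g. grip onsets lagging a visual cue by
400–800 ms) are assigned to the slice whose excitation time is nearest,
ties resolved toward the earlier slice; quantization error ≤ slice TR / 2.
A `floor` mode (slice currently being acquired) is available; which rule a
given lab used is generally unreported, so the choice is explicit.

## Preprocessing

Drift removal runs on the **original** series, before reshuffling: a
voxel-wise least-squares polynomial (order 2 by default) over volume index
is subtracted. Each voxel's samples are uniformly spaced in time (offset by
its slice position), so polynomial drift in acquisition time is polynomial
in volume index of the same order and is annihilated exactly. The voxel
temporal mean is added back by default (`keep_mean=True`) so that tSNR
remains meaningful; detrending is idempotent either way. Detrending is
per-run by default with a per-block option (reshuffling one block at a time
after a per-run detrend is the default pipeline). Motion correction is
deliberately not implemented: volume realignment interpolates across slices
with different epoch timing and so degrades the very resolution the method
buys; the pipeline accepts an externally realigned series instead.

Task repeats (one filled pseudo series per task block) are averaged
slot-wise; output `fill_count` counts contributing repeats per slot, so
partial coverages merge to their union. Averaging `R` i.i.d.-noise repeats
scales slot noise by `1/√R` and median voxel tSNR by `√R` (2 for the four
canonical task blocks).

## Simulator

`generate_run` emulates 2D slice-wise acquisition: all voxels of a slice
share one excitation instant; the value of a voxel in slice `s`, volume `v`
is

```
baseline · (1 + Σ_task events h(t − t_event)/100) + drift(t) + N(0, σ²)
```

at `t = (v·S + acq_index(s)) · T/S`. The baseline is the spoiled
steady-state signal `M0·sin α·(1−E1)/(1−E1·cos α)`, `E1 = e^{−T/T1}`
(defaults T1 = 1 s, flip 73°, M0 = 1000 — a long-TR 7T-style acquisition).
Noise σ is usually set via `calibrate_noise(target_tsnr, baseline)`
(target 50 by default in examples). Drift is at most quadratic in seconds,
chosen so the order-2 detrend closes the loop exactly. Runs are bit
reproducible from `NoiseSpec.seed`.

### HRF

No standard equation exists for the responses the method was demonstrated
on, so the simulator uses the conventional parametric form: a difference of
two gamma densities (peak delay 6 s, undershoot delay 16 s, dispersions
1 s, undershoot ratio 1/6) plus an optional early-dip gamma term (delay
1 s, dispersion 0.25 s, amplitude as a fraction of the positive peak) to
mimic the initial dip reported in visual cortex. The curve is scaled so the
positive peak equals `response_amplitude` (percent signal change; default
2%), is zero at t = 0, and is truncated to zero beyond `support_s`
(default 32 s, the conventional evaluation window).

`GroundTruth` is the *single-event* response sampled on the pseudo grid
`(0, T/S, 2·T/S, …)`. With the canonical 20.1-s inter-stimulus interval, a
response longer than the interval overlaps the next epoch, and the
reshuffled epoch then equals the steady-state superposition rather than the
single-event curve. The exact-recovery tests therefore use
`support_s ≤ 20 s` — the condition under which single-event recovery is
mathematically exact — while the default support stays at 32 s for
realistic simulations. This is the main idealization of the generator;
others: no motion, no physiological (cardiac/respiratory) noise spectra, no
T2* decay within the readout, spatially uniform response. Passing tests
therefore validate the combinatorics, timing arithmetic and noise
statistics of the pipeline, not its robustness to structured physiological
confounds.

## Metrics

- `tsnr`: temporal mean / temporal SD (ddof = 1), NaN samples excluded;
  undefined (raises) for constant series.
- `cnr`: (mean over response window − mean over baseline window) /
  baseline-window SD. No standard window definition exists; the default is
  heuristic — baseline = pseudo volumes 0–9 (pre-response), response = 10
  volumes centered on the empirical peak — and is recorded in the metrics
  report so results are interpretable.
- `ernst_angle(tr, t1) = arccos(e^{−tr/t1})` in degrees;
  `steady_state_ratio` compares two TRs each at its own Ernst angle (the
  comparison is insensitive to using 90° for the long-TR arm: both give
  ≈ 0.26 for 0.1 s vs 2 s at T1 = 1 s).

## Numerical choices and problem sizes

- All internal indices 0-based; logs and examples print 1-based
  slice/volume labels where that matches scanner convention.
- Internal timing in ms; events files in seconds (BIDS), exact at 3
  decimals; NIfTI pixdim[4] in seconds, rounded to µs on read (pixdim is
  float32).
- HRF peak normalization on a 5-ms grid over the support.
- Exactness assertions use 1e-9 relative tolerance; the pipeline achieves
  ~1e-15 in practice.
- Test and acceptance simulations use small phantoms (2×2 to 8×8 in-plane,
  20 slices, one to five 201-volume blocks) — the reshuffle is linear in
  voxels, so small in-plane grids exercise every code path; the tSNR-gain
  measurement uses 20 independent seed sets of four 8×8×20×200 repeats.

## Known limitations

- No GLM/statistical modeling of the pseudo series: its altered covariance
  structure (adjacent acquisitions 20 samples apart) needs dedicated
  treatment before standard inference applies.
- Interleaved slice orders are supported through the permutation and
  round-trip tested, but the canonical design and all quoted budgets assume
  ascending acquisition.
- The control block is reshuffled with the same nominal schedule as task
  blocks (cue times), a choice, since no response times exist without a
  task.
- Whether measured-onset reshuffling should use `nearest` or `floor`
  snapping is an open convention; both are exposed.
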