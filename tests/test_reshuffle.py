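"""The reshuffling operator: mapping, application, inversion, coverage."""

import numpy as np
import pytest

from hihi import (
    AcquisitionGeometry,
    EpiTimeSeries,
    ParadigmDesign,
    StimulusEvent,
    StimulusSchedule,
    apply_reshuffle,
    build_mapping,
    build_schedule,
    invert_reshuffle,
    total_volumes,
    validate_coverage,
)

from conftest import small_setup


def brute_force_slots(schedule, geometry, n_epoch_volumes):
    """Independent oracle: accumulate (slice, pseudo_volume) slot sources by
    explicit per-slice iteration."""
    slots = {}
    for j, e in enumerate(schedule):
        for i in range(n_epoch_volumes * geometry.n_slices):
            k = e.global_slice_index + i
            pos = geometry.slice_order[k % geometry.n_slices]
            slots.setdefault((pos, i), []).append((k // geometry.n_slices, pos))
    return slots


def make_series(geometry, n_volumes, seed=0):
    rng = np.random.default_rng(seed)
    data = rng.normal(100.0, 5.0, size=(3, 2, geometry.n_slices, n_volumes))
    return EpiTimeSeries(data=data, geometry=geometry)


class TestBuildMapping:
    def test_slices_land_at_their_post_stimulus_offset(self):
        """A stimulus during slice 17 (0-based) of volume 0 puts that slice
        into pseudo volume 0; the next acquired slice (position 18, 100 ms
        later) into pseudo volume 1."""
        g = AcquisitionGeometry(n_slices=20, volume_tr=2000)
        d = ParadigmDesign(n_stimuli_per_block=1, n_epoch_volumes=10)
        s = build_schedule(d, g, start_slice_index=17)
        m = build_mapping(s, g, 10)
        assert m.slice_pos[0] == 17 and m.pseudo_volume[0] == 0
        assert m.orig_volume[0] == 0
        assert m.slice_pos[1] == 18 and m.pseudo_volume[1] == 1
        # 200 successive slices spread over 200 pseudo volumes
        assert len(m) == 200
        assert (m.pseudo_volume == np.arange(200)).all()

    def test_minimal_single_record(self):
        g = AcquisitionGeometry(n_slices=1, volume_tr=100)
        s = StimulusSchedule(events=(StimulusEvent(0, 0.0, 0, True),))
        m = build_mapping(s, g, 1)
        assert len(m) == 1
        assert m.pseudo_volume[0] == 0 and m.slice_pos[0] == 0

    def test_canonical_small_block_covers_every_slot_once(self):
        g, d, s = small_setup(n_slices=3, n_epoch_volumes=2, volume_tr=300.0)
        m = build_mapping(s, g, 2)
        oracle = brute_force_slots(s, g, 2)
        assert len(oracle) == 6 * 3
        assert all(len(v) == 1 for v in oracle.values())
        got = set(zip(m.slice_pos.tolist(), m.pseudo_volume.tolist()))
        assert got == set(oracle)

    @pytest.mark.parametrize("n_slices", range(2, 9))
    @pytest.mark.parametrize("n_epoch_volumes", [1, 2, 3])
    def test_bijection_for_canonical_schedules(self, n_slices, n_epoch_volumes):
        """One-slice-shift schedules with one stimulus per slice map
        bijectively onto the full (slice, pseudo volume) grid."""
        g, d, s = small_setup(n_slices=n_slices, n_epoch_volumes=n_epoch_volumes,
                              volume_tr=100.0 * n_slices)
        m = build_mapping(s, g, n_epoch_volumes)
        pairs = list(zip(m.slice_pos.tolist(), m.pseudo_volume.tolist()))
        assert len(pairs) == len(set(pairs)) == n_slices * n_epoch_volumes * n_slices

    def test_timing_identity_within_pseudo_volumes(self, canonical_schedule,
                                                   canonical_geometry):
        """Every record satisfies (source slice index − event onset slice)
        == pseudo_volume: all slices of pseudo volume i were acquired
        exactly i slice-TRs post stimulus (built-in slice-time correction)."""
        m = build_mapping(canonical_schedule, canonical_geometry, 10,
                          n_run_volumes=1015)
        q = np.array([e.global_slice_index for e in canonical_schedule])
        src_global = m.orig_volume * 20 + np.array(
            [canonical_geometry.acquisition_index(p) for p in m.slice_pos]
        )
        assert (src_global - q[m.event] == m.pseudo_volume).all()

    def test_adjacent_original_volumes_are_n_slices_apart(self,
                                                          canonical_schedule,
                                                          canonical_geometry):
        m = build_mapping(canonical_schedule, canonical_geometry, 10,
                          n_run_volumes=1015)
        ev0 = m.event == 0
        pos = m.slice_pos[ev0]
        for p in (0, 7, 19):
            vols = m.orig_volume[ev0][pos == p]
            pvs = m.pseudo_volume[ev0][pos == p]
            order = np.argsort(vols)
            assert (np.diff(vols[order]) == 1).all()
            assert (np.diff(pvs[order]) == 20).all()

    def test_epoch_overrun_raises(self):
        g, d, s = small_setup(n_slices=4, n_epoch_volumes=2)
        with pytest.raises(ValueError, match="overrun"):
            build_mapping(s, g, 2, n_run_volumes=total_volumes(d, g) - 1)

    def test_overlapping_epochs_warn(self):
        g = AcquisitionGeometry(n_slices=2, volume_tr=200)
        s = StimulusSchedule(events=(
            StimulusEvent(0, 0.0, 0, True), StimulusEvent(1, 100.0, 0, True),
        ))
        with pytest.warns(UserWarning, match="overlap"):
            build_mapping(s, g, 2)

    def test_interleaved_slice_order_preserves_position(self):
        g = AcquisitionGeometry(n_slices=4, volume_tr=400,
                                slice_order=(0, 2, 1, 3))
        d = ParadigmDesign(n_stimuli_per_block=4, n_epoch_volumes=1)
        s = build_schedule(d, g)
        m = build_mapping(s, g, 1)
        oracle = brute_force_slots(s, g, 1)
        assert all(len(v) == 1 for v in oracle.values())
        assert set(zip(m.slice_pos.tolist(), m.pseudo_volume.tolist())) == set(oracle)


class TestApplyReshuffle:
    def test_canonical_fill_is_one_and_copies_bit_identical(self):
        g, d, s = small_setup(n_slices=4, n_epoch_volumes=2)
        series = make_series(g, total_volumes(d, g))
        m = build_mapping(s, g, 2, n_run_volumes=series.n_volumes)
        h = apply_reshuffle(series, m)
        assert (h.fill_count == 1).all()
        assert h.pseudo_volume_tr == g.slice_tr
        # every slot is an exact copy of its unique source slice
        for r in range(len(m)):
            np.testing.assert_array_equal(
                h.data[:, :, m.slice_pos[r], m.pseudo_volume[r]],
                series.data[:, :, m.slice_pos[r], m.orig_volume[r]],
            )

    def test_empty_mapping_gives_all_missing(self):
        g = AcquisitionGeometry(n_slices=2, volume_tr=200)
        series = make_series(g, 4)
        m = build_mapping(StimulusSchedule(events=()), g, 2)
        h = apply_reshuffle(series, m)
        assert (h.fill_count == 0).all()
        assert np.isnan(h.data).all()

    def test_duplicate_slots_hold_the_mean(self):
        """Two events with the same slice phase map each slot twice; the
        slot value must equal the mean of both sources (oracle: explicit
        per-slot accumulation)."""
        g = AcquisitionGeometry(n_slices=2, volume_tr=200)
        s = StimulusSchedule(events=(
            StimulusEvent(0, 0.0, 0, True), StimulusEvent(4, 400.0, 0, True),
        ))
        series = make_series(g, 6, seed=3)
        m = build_mapping(s, g, 1)
        h = apply_reshuffle(series, m)
        # same slice phase: the two epochs hit the same slots twice and
        # leave the complementary slots empty
        oracle = brute_force_slots(s, g, 1)
        assert all(len(v) == 2 for v in oracle.values())
        for pos in range(2):
            for pv in range(2):
                expected_fill = 2 if (pos, pv) in oracle else 0
                assert h.fill_count[pos, pv] == expected_fill
        for (pos, pv), sources in oracle.items():
            expected = np.mean(
                [series.data[:, :, p, v] for v, p in sources], axis=0
            )
            np.testing.assert_allclose(h.data[:, :, pos, pv], expected,
                                       rtol=1e-12)

    def test_value_conservation(self):
        """Sum of mapped source samples equals sum over slots of value x
        fill_count."""
        g, d, s = small_setup(n_slices=5, n_epoch_volumes=2, volume_tr=500.0)
        series = make_series(g, total_volumes(d, g), seed=7)
        m = build_mapping(s, g, 2, n_run_volumes=series.n_volumes)
        h = apply_reshuffle(series, m)
        src_sum = series.data[:, :, m.slice_pos, m.orig_volume].sum()
        slot_sum = np.nansum(h.data * h.fill_count[None, None], )
        assert abs(src_sum - slot_sum) <= 1e-9 * abs(src_sum)

    def test_dimension_mismatch_raises(self):
        g, d, s = small_setup(n_slices=4, n_epoch_volumes=2)
        series = make_series(g, 3)  # too short for the mapping
        m = build_mapping(s, g, 2)
        with pytest.raises(ValueError):
            apply_reshuffle(series, m)


class TestInvertReshuffle:
    def test_round_trip_restores_mapped_slices(self):
        g, d, s = small_setup(n_slices=4, n_epoch_volumes=2)
        series = make_series(g, total_volumes(d, g), seed=11)
        m = build_mapping(s, g, 2, n_run_volumes=series.n_volumes)
        back = invert_reshuffle(apply_reshuffle(series, m), m, series.n_volumes)
        mask = np.zeros(series.data.shape, dtype=bool)
        mask[:, :, m.slice_pos, m.orig_volume] = True
        np.testing.assert_array_equal(back.data[mask], series.data[mask])
        assert np.isnan(back.data[~mask]).all()

    def test_empty_mapping_round_trip_all_missing(self):
        g = AcquisitionGeometry(n_slices=2, volume_tr=200)
        series = make_series(g, 4)
        m = build_mapping(StimulusSchedule(events=()), g, 2)
        back = invert_reshuffle(apply_reshuffle(series, m), m, 4)
        assert np.isnan(back.data).all()

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_random_small_configs_round_trip(self, seed):
        rng = np.random.default_rng(seed)
        n_slices = int(rng.integers(2, 7))
        n_epoch = int(rng.integers(1, 4))
        g, d, s = small_setup(n_slices=n_slices, n_epoch_volumes=n_epoch,
                              volume_tr=100.0 * n_slices)
        series = make_series(g, total_volumes(d, g), seed=seed)
        m = build_mapping(s, g, n_epoch, n_run_volumes=series.n_volumes)
        back = invert_reshuffle(apply_reshuffle(series, m), m, series.n_volumes)
        np.testing.assert_array_equal(
            back.data[:, :, m.slice_pos, m.orig_volume],
            series.data[:, :, m.slice_pos, m.orig_volume],
        )

    def test_averaged_slots_cannot_be_inverted(self):
        g = AcquisitionGeometry(n_slices=2, volume_tr=200)
        s = StimulusSchedule(events=(
            StimulusEvent(0, 0.0, 0, True), StimulusEvent(4, 400.0, 0, True),
        ))
        series = make_series(g, 6)
        m = build_mapping(s, g, 1)
        h = apply_reshuffle(series, m)
        with pytest.raises(ValueError, match="invert"):
            invert_reshuffle(h, m, 6)


class TestCoverage:
    def test_canonical_block_is_complete(self, canonical_schedule,
                                         canonical_geometry):
        m = build_mapping(canonical_schedule, canonical_geometry, 10,
                          n_run_volumes=1015, blocks={0})
        rep = validate_coverage(m, canonical_geometry, 10)
        assert rep.n_empty == 0 and rep.n_multiple == 0
        assert rep.complete

    def test_missing_event_leaves_one_slot_per_pseudo_volume(
        self, canonical_schedule, canonical_geometry
    ):
        block0 = [e for e in canonical_schedule if e.block == 0]
        reduced = StimulusSchedule(events=tuple(block0[:-1]))
        m = build_mapping(reduced, canonical_geometry, 10)
        rep = validate_coverage(m, canonical_geometry, 10)
        assert rep.n_empty == 200  # the missing event's 10*20 slots
        assert (rep.fill_count.sum(axis=0) == 19).all()

    def test_single_event_fills_one_slot_per_pseudo_volume(
        self, canonical_geometry
    ):
        s = StimulusSchedule(events=(StimulusEvent(17, 1700.0, 0, True),))
        m = build_mapping(s, canonical_geometry, 10)
        rep = validate_coverage(m, canonical_geometry, 10)
        assert (rep.fill_count.sum(axis=0) == 1).all()
        assert rep.n_empty == 200 * 20 - 200
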