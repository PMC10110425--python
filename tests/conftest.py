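import pytest

from hihi import AcquisitionGeometry, ParadigmDesign, build_schedule


@pytest.fixture
def canonical_geometry():
    """20 slices, 2-s volume TR, ascending order -> 100-ms slice TR."""
    return AcquisitionGeometry(n_slices=20, volume_tr=2000.0)


@pytest.fixture
def canonical_design():
    """20 stimuli x 10 epoch volumes, 5 blocks (4 task + 1 control), 5+5 dummies."""
    return ParadigmDesign(
        n_stimuli_per_block=20,
        n_epoch_volumes=10,
        n_blocks=5,
        task_block_flags=(True, True, True, True, False),
        n_dummy_start=5,
        n_dummy_end=5,
    )


@pytest.fixture
def canonical_schedule(canonical_design, canonical_geometry):
    return build_schedule(canonical_design, canonical_geometry)


def small_setup(n_slices=4, n_epoch_volumes=2, n_blocks=1, volume_tr=400.0,
                **kwargs):
    """Small full-coverage paradigm for exhaustive checks."""
    geometry = AcquisitionGeometry(n_slices=n_slices, volume_tr=volume_tr)
    design = ParadigmDesign(
        n_stimuli_per_block=n_slices,
        n_epoch_volumes=n_epoch_volumes,
        n_blocks=n_blocks,
        **kwargs,
    )
    return geometry, design, build_schedule(design, geometry)
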