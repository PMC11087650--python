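import numpy as np
import pytest

from nigraquant import CohortConfig, PhantomGeometry, RoiMask, VolumeImage, generate_cohort

VOX = (0.35, 0.35, 3.0)


def make_mask(shape, voxels, voxel_size=VOX, label="rater"):
    """RoiMask from an iterable of (x, y, z) voxel coordinates."""
    data = np.zeros(shape, dtype=bool)
    for v in voxels:
        data[tuple(v)] = True
    return RoiMask(data=data, voxel_size_mm=voxel_size, label=label)


def make_image(data, voxel_size=VOX):
    return VolumeImage(data=np.asarray(data, dtype=np.float32), voxel_size_mm=voxel_size)


@pytest.fixture(scope="session")
def geometry():
    return PhantomGeometry(grid_shape=(112, 112, 7), voxel_size_mm=VOX)


@pytest.fixture(scope="session")
def default_cohort():
    """The default study-sized cohort (30 HC / 15 LRRK2 / 22 PD, seed 0)."""
    return generate_cohort(CohortConfig(seed=0))


@pytest.fixture(scope="session")
def small_cohort():
    """A small but analysis-complete cohort for pipeline-level tests."""
    return generate_cohort(CohortConfig(n_hc=6, n_lrrk2=5, n_pd=6, seed=3))


@pytest.fixture(scope="session")
def repeated_run_dirs(tmp_path_factory):
    """The same small end-to-end run executed twice into separate directories."""
    from nigraquant import RunConfig, StatsConfig, run_pipeline

    cfg = RunConfig(
        cohort=CohortConfig(n_hc=6, n_lrrk2=5, n_pd=6, seed=3),
        stats=StatsConfig(n_perm=1000),
    )
    dirs = []
    for name in ("run_a", "run_b"):
        out = tmp_path_factory.mktemp(name)
        run_pipeline(cfg, out_dir=out)
        dirs.append(out)
    return tuple(dirs)
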