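import numpy as np
import pytest

from sufseg import RunConfig, build_dataset, generate_skull_phantom, train


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def phantom32():
    """A 32-voxel, 1 mm skull phantom shared by read-only tests."""
    return generate_skull_phantom(seed=7, grid_shape=(32, 32, 32), spacing_mm=1.0)


@pytest.fixture(scope="session")
def micro_manifest():
    """Small in-memory corpus (3 skulls x 7 defects at 16^3 / 2.5 mm)."""
    return build_dataset(
        n_skulls=3,
        out_dir="unused",
        defects_per_skull=7,
        region_counts=(1,) * 7,
        complexity_counts_per_skull=(3, 2, 2),
        test_fraction_of_skulls=0.34,
        seed=5,
        grid_shape=(16, 16, 16),
        spacing_mm=2.5,
        write_volumes=False,
    )


@pytest.fixture(scope="session")
def micro_train(micro_manifest):
    """One short seeded training run reused across pipeline tests."""
    cfg = RunConfig.micro(seed=3)
    return cfg, train(cfg, micro_manifest)
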