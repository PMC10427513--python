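import numpy as np
import pytest

from airwayfat import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def noiseless_phantom():
    """Default 64-cube noiseless phantom shared across read-only tests."""
    return generate_phantom(PhantomSpec())


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def random_dixon(rng, shape=(4, 4, 4), spacing=(1.0, 1.0, 1.0)):
    """Random non-negative Dixon set for oracle comparisons."""
    from airwayfat import DixonSet, VolumeImage

    fat = rng.uniform(0.0, 100.0, shape)
    water = rng.uniform(0.0, 100.0, shape)
    return DixonSet(
        in_phase=VolumeImage(fat + water, spacing),
        out_phase=VolumeImage(np.abs(water - fat), spacing),
        fat=VolumeImage(fat, spacing),
        water=VolumeImage(water, spacing),
    )
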