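import numpy as np
import pytest

from egopool import SyntheticSpec, gen_dataset
from egopool.manifest_io import FeatureCache


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def separable_dataset(tmp_path_factory):
    """Separable synthetic dataset in cached-stack form (smaller channel count
    than the pool5 default to keep the suite fast; geometry is unchanged)."""
    root = tmp_path_factory.mktemp("separable")
    spec = SyntheticSpec(seed=7, channels=64)
    manifest = gen_dataset(spec, root, form="stacks")
    return spec, manifest, FeatureCache(root / "cache")


@pytest.fixture(scope="session")
def shuffled_dataset(tmp_path_factory):
    """Pure-noise dataset with permuted labels: a chance-level control."""
    root = tmp_path_factory.mktemp("shuffled")
    spec = SyntheticSpec(seed=11, channels=64, signal_strength=0.0,
                         n_subjects=4, clips_per_subject_class=3)
    manifest = gen_dataset(spec, root, form="stacks", shuffle_labels=True)
    return spec, manifest, FeatureCache(root / "cache")
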