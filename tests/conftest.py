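import numpy as np
import pytest

import wingmorph as wm


def random_configuration(rng, k=8, sid="s", spread=1.0):
    """A random non-degenerate landmark configuration."""
    return wm.LandmarkConfiguration(sid, spread * rng.normal(size=(k, 2)))


def random_similarity(rng, coords):
    """Apply a random rotation, positive scaling and translation."""
    theta = rng.uniform(0, 2 * np.pi)
    c, s = np.cos(theta), np.sin(theta)
    rot = np.array([[c, s], [-s, c]])
    scale = float(np.exp(rng.uniform(-1.5, 1.5)))
    shift = rng.uniform(-5, 5, size=2)
    return scale * coords @ rot + shift


@pytest.fixture
def rng():
    return np.random.default_rng(20171019)


@pytest.fixture(scope="session")
def separable_dataset():
    """Four well-separated groups, one hierarchy level, 10 specimens each."""
    spec = wm.SyntheticSpec(
        hierarchy=(("group", 4),), n_per_group=10, within_sd=0.01, separation=10.0, seed=7
    )
    return spec, wm.generate_dataset(spec)


@pytest.fixture(scope="session")
def separable_aligned(separable_dataset):
    spec, ds = separable_dataset
    aligned = wm.gpa(ds)
    groups = ds.labels.groups_at(aligned.specimen_ids, "group")
    return spec, ds, aligned, groups
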