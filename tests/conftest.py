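import numpy as np
import pytest

from nbic import Bicluster


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_bicluster(rng, n_subjects=30, n_features=8):
    """A random nonempty bicluster over integer subject/feature universes."""
    ns = rng.integers(1, n_subjects + 1)
    nf = rng.integers(1, n_features + 1)
    subjects = rng.choice(n_subjects, size=ns, replace=False)
    features = rng.choice(n_features, size=nf, replace=False)
    return Bicluster(frozenset(int(s) for s in subjects), frozenset(int(f) for f in features))


def cell_dice(a: Bicluster, b: Bicluster) -> float:
    """Independent oracle: dice coefficient over explicit (subject, feature) cells."""
    cells_a = {(s, f) for s in a.subject_set for f in a.feature_set}
    cells_b = {(s, f) for s in b.subject_set for f in b.feature_set}
    return 2 * len(cells_a & cells_b) / (len(cells_a) + len(cells_b))
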