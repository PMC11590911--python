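import numpy as np
import pytest

from snpld import MISSING, make_panel


def random_panel(seed, n_samples=None, n_loci=None, missing_rate=0.1):
    """Random canonical-orientation panel for round-trip/property tests."""
    rng = np.random.default_rng(seed)
    ns = int(n_samples if n_samples is not None else rng.integers(2, 9))
    nl = int(n_loci if n_loci is not None else rng.integers(1, 13))
    d = rng.integers(0, 3, size=(ns, nl)).astype(np.int8)
    d[rng.random(d.shape) < missing_rate] = MISSING
    return make_panel(d).canonicalize_orientation()


@pytest.fixture
def rng():
    return np.random.default_rng(0)
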