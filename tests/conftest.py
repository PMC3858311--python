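import numpy as np
import pytest

from epistasis_cmi import table_from_counts


@pytest.fixture
def rng():
    return np.random.default_rng(20131210)


@pytest.fixture
def random_table(rng):
    """Factory for random strictly-positive 3x3 stratified tables."""

    def make(n_case=500, n_control=500, r=3, c=3, seed=None):
        g = rng if seed is None else np.random.default_rng(seed)
        case = g.multinomial(n_case, np.full(r * c, 1 / (r * c))).reshape(r, c)
        ctrl = g.multinomial(n_control, np.full(r * c, 1 / (r * c))).reshape(r, c)
        return table_from_counts(case, ctrl, tuple(range(r)), tuple(range(c)))

    return make
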