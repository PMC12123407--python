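import numpy as np
import pytest

from kivcn import simulator as sim

# small locus for fast unit tests; acceptance tests use the full-scale defaults
SMALL_LOCUS = dict(
    unit_length=550,
    n_units=6,
    divergence=0.005,
    norm_length=3000,
    flank_length=500,
)
SMALL_K = 21


@pytest.fixture(scope="session")
def small_template():
    rng = np.random.default_rng(np.random.SeedSequence(777))
    return sim.make_locus_template(rng, **SMALL_LOCUS)


@pytest.fixture(scope="session")
def small_db(small_template):
    return small_template.build_database(k=SMALL_K)
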