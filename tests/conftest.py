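import numpy as np
import pytest
from hypothesis import settings

import confaudit as ca

settings.register_profile("default", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("default")


@pytest.fixture(scope="session")
def paper_cohort():
    """One paper-structure synthetic cohort, zlog-transformed, fixed seed."""
    spec = ca.paper_default_spec()
    table, meta = ca.generate_cohort(spec, seed=7)
    return spec, ca.add_zlog_features(table), ca.metadata_frame(meta)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
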