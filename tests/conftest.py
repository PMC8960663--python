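import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import exonkit as ek

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow,
                           HealthCheck.function_scoped_fixture])
settings.load_profile("ci")


@pytest.fixture
def toy_genome():
    """Two small chromosomes with known sequence."""
    return ek.GenomeSequence({
        "c1": "AACCGGTT" * 10,      # 80 bp
        "c2": "ACGTACGT",           # palindromic under revcomp
    })


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)
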