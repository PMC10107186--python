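import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from nichemix.tables_io import IsotopeTriple, SourceGroup, TEFScenario


def make_source(i, mean, sd, conc=0.5, nutrients=None):
    """A minimal SourceGroup with equal element concentrations."""
    c = conc if isinstance(conc, dict) else {"C": conc, "N": conc, "S": conc}
    return SourceGroup(
        group_id=i,
        label=f"s{i}",
        members=(),
        n_total=1,
        iso_mean=IsotopeTriple(*mean),
        iso_sd=IsotopeTriple(*sd),
        conc=c,
        nutrients=nutrients,
    )


@pytest.fixture
def zero_tef():
    return TEFScenario("zero", IsotopeTriple(0, 0, 0), IsotopeTriple(0, 0, 0))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
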