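import pytest
from hypothesis import HealthCheck, settings

import wdsqi as w
from wdsqi.io import PRINTED_EIGENVALUES

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def specs():
    return w.Config.default().specs


@pytest.fixture(scope="session")
def correlations():
    return w.load_fixture("correlations")


@pytest.fixture(scope="session")
def printed_pca():
    """PCAResult wrapping the published two-component loading matrix."""
    ld = w.load_fixture("loadings")
    return w.PCAResult.from_loadings(ld[["pc1", "pc2"]], PRINTED_EIGENVALUES)


@pytest.fixture(scope="session")
def memberships():
    return w.load_fixture("memberships")


@pytest.fixture(scope="session")
def synth_study():
    """One synthetic study at the published design size (5 plots x 5 samples)."""
    return w.generate_samples(w.default_config(seed=1, n_per_plot=5))
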