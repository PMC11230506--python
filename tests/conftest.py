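import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, max_examples=25, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def helix_base():
    from gpcrkit.helix import HelixFixtureSpec, make_helix_fixture

    return make_helix_fixture(HelixFixtureSpec(n_residues=20))


@pytest.fixture(scope="session")
def double_well_gamd():
    """One full staged accelerated-sampling run on the 1-D double well,
    shared by the reweighting and acceptance checks."""
    from gpcrkit.gamd import GaMDProtocol, run_protocol
    from gpcrkit.potentials import make_double_well

    model = make_double_well(1.0, 1.0)
    protocol = GaMDProtocol(dt=0.01, n_cmd=100_000, n_equil=200_000,
                            n_production=400_000, stats_cadence=10_000,
                            mode="single", replicas=3, save_every=10)
    return model, protocol, run_protocol(model, protocol, seed=2024)
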