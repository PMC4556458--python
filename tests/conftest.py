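import numpy as np
import pytest

from tidalstm import fixtures as fx
from tidalstm.demography import SizeClassScheme, VitalRates, build_transition_matrix


@pytest.fixture(scope="session")
def community():
    """Three-species synthetic community (fast / slow / pioneer), fixed seed."""
    return fx.demo_community(seed=1)


@pytest.fixture(scope="session")
def stand(community):
    return fx.demo_stand(community)


@pytest.fixture(scope="session")
def damage(community, stand):
    return fx.default_damage_params(stand, community)


@pytest.fixture()
def toy_scheme():
    return SizeClassScheme((5.0, 10.0, 12.5))


@pytest.fixture()
def toy_rates():
    return VitalRates(
        S=np.array([0.95, 0.96, 0.97]),
        G=np.array([0.10, 0.08, 0.0]),
        F=np.array([0.0, 0.0, 0.5]),
        x=np.array([0.0, 0.1, 0.0]),
    )


@pytest.fixture()
def toy_matrix(toy_rates, toy_scheme):
    return build_transition_matrix(toy_rates, toy_scheme)


def random_primitive_matrix(rng, n=5, lam_scale=None):
    """Dense positive matrix, optionally rescaled to a target spectral radius."""
    A = rng.uniform(0.05, 1.0, size=(n, n))
    if lam_scale is not None:
        from tidalstm.demography import spectral_radius

        A *= lam_scale / spectral_radius(A)
    return A
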