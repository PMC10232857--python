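import numpy as np
import pytest

import fedmsrw as fm


@pytest.fixture(scope="session")
def small_profile():
    return fm.ClientProfile(
        client_id="C1",
        n_cases=4,
        volume_shape=(24, 24, 24),
        target_ratio=0.02,
        noise_sigma=2.0,
    )


@pytest.fixture(scope="session")
def small_case(small_profile):
    return fm.generate_case(small_profile, rng_seed=7)


@pytest.fixture(scope="session")
def tiny_net_cfg():
    return fm.NetworkConfig(in_channels=1, depth=2, base_channels=2)


@pytest.fixture(scope="session")
def tiny_net(tiny_net_cfg):
    return fm.build_network(tiny_net_cfg, rng_seed=0)


@pytest.fixture(scope="session")
def toy_federation():
    """Two small clients with distinct intensity and lesion-burden profiles."""
    profiles = [
        fm.ClientProfile(
            client_id="A", n_cases=3, volume_shape=(16, 16, 16),
            target_ratio=0.03, intensity_offset=0.0,
            lesion_radius_range=(1.0, 2.0),
        ),
        fm.ClientProfile(
            client_id="B", n_cases=3, volume_shape=(16, 16, 16),
            target_ratio=0.06, intensity_offset=40.0,
            lesion_radius_range=(1.0, 2.0),
        ),
    ]
    return fm.generate_federation(profiles, rng_seed=11)


def toy_fed_config(mode, **overrides):
    kwargs = dict(
        mode=mode,
        n_rounds=3,
        iters_per_round=4,
        lr=5e-3,
        batch_size=2,
        patch_size=(8, 8, 8),
        master_seed=5,
    )
    kwargs.update(overrides)
    return fm.FederationConfig(**kwargs)


@pytest.fixture(scope="session")
def toy_net_cfg():
    return fm.NetworkConfig(in_channels=1, depth=1, base_channels=2)
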