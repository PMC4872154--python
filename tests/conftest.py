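import numpy as np
import pytest

import smtseq as s


@pytest.fixture(scope="session")
def refs():
    """Default eight-template reference panel, fixed seed."""
    return s.make_references(8, seed=7)


@pytest.fixture(scope="session")
def protocol():
    return s.FlowProtocol()


@pytest.fixture()
def grid_molecules(refs):
    """15 isolated single-occupancy molecules on a regular grid."""
    rng = np.random.default_rng(2)
    n = 15
    xs = (np.arange(n) % 4) * 30 + 15 + rng.uniform(-3, 3, n)
    ys = (np.arange(n) // 4) * 30 + 15 + rng.uniform(-3, 3, n)
    return s.MoleculeSet(
        x=xs,
        y=ys,
        template_index=rng.integers(0, 8, n).astype(np.int32),
        origin=np.zeros(n, dtype=np.int8),
        site_index=np.arange(n),
        site_occupancy=np.ones(n, dtype=int),
    )


@pytest.fixture(scope="session")
def noise_free_optics():
    return s.OpticsConfig(
        shot_noise=False,
        background_level=0.0,
        read_noise_sigma=0.0,
        drift_per_cycle_sigma=0.0,
    )
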