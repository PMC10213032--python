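import warnings

import numpy as np
import pytest

import mycelia as m


@pytest.fixture(scope="session")
def ref_traj():
    """One M2-calibrated reference thallus, 13 h of growth."""
    return m.run(m.reference_config(seed=3, t_end_h=13.0))


@pytest.fixture(scope="session")
def ref_series(ref_traj):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return m.density_series(ref_traj, bootstrap=100,
                                rng=np.random.default_rng(0),
                                keep_replicates=True)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
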