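import numpy as np
import pytest

from burstcycle import AgeModelParams


@pytest.fixture(scope="session")
def ref_age_params() -> AgeModelParams:
    """A moderately expressed gene with halved post-replication burst
    frequency and mild age scaling of the burst size."""
    return AgeModelParams(
        f1=0.7, f2=0.35, rho1=2.0, rho2=2.0,
        betas=(0.4, -0.3, 0.5, 0.3), d=0.1, T=13.25,
    )


@pytest.fixture(scope="session")
def theta_cells() -> np.ndarray:
    rng = np.random.default_rng(7)
    return np.round(rng.choice(np.round(np.arange(100) * 0.01, 2), size=4000), 2)
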