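import numpy as np
import pytest

from tensorbasket.simulate import SyntheticConfig, simulate_tensor
from tensorbasket.tensor import PurchaseTensor


@pytest.fixture
def tiny_tensor():
    """3 customers × 2 groups × 4 weeks with simple integer entries."""
    rng = np.random.default_rng(0)
    values = rng.integers(0, 5, size=(3, 2, 4)).astype(float)
    return PurchaseTensor(values, ["c1", "c2", "c3"], ["ga", "gb"], np.arange(1, 5))


@pytest.fixture
def gaussian_separable():
    """Moderate separable gaussian-mode data with its ground truth."""
    config = SyntheticConfig(
        n_customers=400,
        n_groups=10,
        n_weeks=8,
        true_ranks=(3, 2),
        latent_sds=(16.0, 13.0, 11.0, 9.0, 7.0, 5.0),
        noise_sd=1.0,
        mean_matrix_scale=0.0,
        holiday_weeks=(),
        zero_inflation_prob=(0.0,) * 10,
        mode="gaussian",
        seed=101,
    )
    return simulate_tensor(config)


@pytest.fixture
def expenditure_default():
    """Default expenditure-mode loyalty-card year, 400 customers."""
    return simulate_tensor(SyntheticConfig(n_customers=400, seed=7))
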