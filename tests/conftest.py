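import numpy as np
import pytest

from dualcsia.simulate import SimulationConfig, simulate_rayleigh_series

F_GRID = tuple(round(0.9 - 0.1 * i, 10) for i in range(9))


@pytest.fixture
def noiseless_series():
    """Exact Rayleigh distillation, delta0 = 0 both elements, single shots."""
    cfg = SimulationConfig(
        epsilon_c=-27.5,
        epsilon_cl=-5.3,
        delta0_c=0.0,
        delta0_cl=0.0,
        noise_sd=0.0,
        n_replicates=1,
    )
    return simulate_rayleigh_series(cfg, "1,2-DCA", "1,2-DCA")


@pytest.fixture
def noisy_series():
    """Default assay design: 9 vials, triplicates, 0.5 permil noise."""
    cfg = SimulationConfig(epsilon_c=-27.5, epsilon_cl=-5.3, seed=42)
    return simulate_rayleigh_series(cfg, "1,2-DCA", "1,2-DCA")


def ols_slope(x, y):
    """Independent closed-form OLS slope oracle (no model code involved)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xc = x - x.mean()
    return float((xc * (y - y.mean())).sum() / (xc * xc).sum())
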