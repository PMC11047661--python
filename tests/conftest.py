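import numpy as np
import pytest

from ocuscreen import SimChipConfig, simulate_chip_image


@pytest.fixture(scope="session")
def noiseless_chip():
    """Small noiseless chip with a half-apoptotic population, exact ground truth."""
    cfg = SimChipConfig(grid_rows=3, grid_cols=3, noise_sd=0.0, seed=42)
    return simulate_chip_image(cfg, 0.5)


@pytest.fixture(scope="session")
def noisy_offset_chip():
    """Chip with rendering noise and a known rigid grid misalignment."""
    cfg = SimChipConfig(
        grid_rows=3, grid_cols=3, noise_sd=2.0, grid_offset_px=(5, -3), seed=7
    )
    return simulate_chip_image(cfg, 0.0)


def truncated_rounded_normal_mean(mu: float, sd: float) -> float:
    """Analytic mean of max(1, round(N(mu, sd))): independent oracle for the
    synthetic cell-count law (discrete sum over the rounded support)."""
    from scipy.stats import norm

    if sd == 0:
        return max(1.0, round(mu))
    ks = np.arange(2, int(mu + 12 * sd) + 1)
    p_k = norm.cdf((ks + 0.5 - mu) / sd) - norm.cdf((ks - 0.5 - mu) / sd)
    p_le1 = norm.cdf((1.5 - mu) / sd)
    return float(p_le1 * 1.0 + (ks * p_k).sum())
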