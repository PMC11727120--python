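import numpy as np
import pytest

from dscout.simulate import PlateSimParams, simulate_plate


@pytest.fixture(scope="session")
def small_plate():
    """A 2000-well single-region plate with known truth, shared read-only."""
    params = PlateSimParams(
        n_wells=2000,
        regions=("protein",),
        target_copies={
            ("protein", "FAM"): 60.0,
            ("protein", "VIC"): 40.0,
            ("protein", "CY5"): 50.0,
        },
        seed=11,
    )
    run, truth = simulate_plate(params)
    return params, run, truth


@pytest.fixture()
def clean_logistic():
    """Noiseless 4PL trace with known parameters (F0=1, drift=0, A=10, k=1.2, c50=26)."""
    c = np.arange(1, 41, dtype=float)
    y = 1.0 + 10.0 / (1.0 + np.exp(-1.2 * (c - 26.0)))
    return c, y, dict(F0=1.0, drift=0.0, A=10.0, k=1.2, c50=26.0)
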