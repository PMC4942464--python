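import numpy as np
import pytest

from p2ensemble.hill_core import DoseResponsePoint, hill_response
from p2ensemble.receptor_catalog import make_basis


@pytest.fixture(scope="session")
def fig_style_basis():
    """Rodent {P2Y1, P2Y4, P2X7} basis used by the two-peak amplitude model."""
    return make_basis(["P2Y1", "P2Y4", "P2X7"], "rodent")


@pytest.fixture(scope="session")
def log_grid():
    return np.logspace(-9, -2, 11)


def hill_points(k_half, hill_coeff, n=12, span=100.0, noise_sd=0.0, seed=None):
    """Noise-free (or noisy) points on a log grid around K1/2."""
    conc = np.logspace(np.log10(k_half / span), np.log10(k_half * span), n)
    resp = hill_response(conc, k_half, hill_coeff)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        resp = resp + rng.normal(0.0, noise_sd, size=n)
    return [DoseResponsePoint(float(c), float(r)) for c, r in zip(conc, resp)]
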