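import numpy as np
import pytest

from metfa import SimulationTruth, generate_met, uniform_designs


def make_truth(
    t: int,
    *,
    k: int = 1,
    gvar: float = 0.15,
    psi: float = 0.0,
    sigma2: float = 0.15,
    rho_col: float = 0.0,
    rho_row: float = 0.0,
    col_var: float = 0.0,
    row_var: float = 0.0,
    lcol_slope: float = 0.0,
    lrow_slope: float = 0.0,
    block_var: float = 0.02,
    seed: int = 0,
    Lambda=None,
) -> SimulationTruth:
    """Convenience truth: equal loadings sqrt(gvar) unless Lambda is given."""
    if Lambda is None:
        Lambda = np.zeros((t, k))
        Lambda[:, 0] = np.sqrt(gvar)
    return SimulationTruth(
        Lambda=Lambda, Psi=np.full(t, psi), sigma2=np.full(t, sigma2),
        rho_col=np.full(t, rho_col), rho_row=np.full(t, rho_row),
        col_var=np.full(t, col_var), row_var=np.full(t, row_var),
        lcol_slope=np.full(t, lcol_slope), lrow_slope=np.full(t, lrow_slope),
        block_var=np.full(t, block_var), trial_mean=np.full(t, 4.0), seed=seed,
    )


@pytest.fixture
def small_trial():
    """One 6x10 trial, 20 entries x 3 reps, mild AR1 in the column direction."""
    designs = uniform_designs(1, 6, 10, 20, 3)
    truth = make_truth(1, sigma2=0.12, rho_col=0.5, block_var=0.03, seed=42)
    d, truth = generate_met(designs, truth)
    return d, truth


@pytest.fixture
def small_met():
    """Four 4x10 trials, 10 shared entries x 4 reps, iid residuals."""
    designs = uniform_designs(4, 4, 10, 10, 4)
    truth = make_truth(4, gvar=0.2, psi=0.05, sigma2=0.1, seed=7)
    d, truth = generate_met(designs, truth)
    return d, truth
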