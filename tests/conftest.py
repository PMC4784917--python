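"""Shared fixtures: the one expensive master-variable sweep is session-scoped."""

from __future__ import annotations

import numpy as np
import pytest

from msbsim import SimulationConfig, sweep_master_variable
from msbsim.simulate import MagnetizationTrace


@pytest.fixture(scope="session")
def fig_sweep():
    """Polydisperse harmonic sweep over the full sigmoid (15 points, n=1e4).

    Varies the mean unitless field at fixed mean unitless frequency 1 with
    10% lognormal size dispersion, spanning A from the linear-response floor
    to square-wave saturation.  Shared by the Langevin-fit, sigmoid-shape
    and sensitivity tests.
    """
    grid = np.logspace(-1, 4, 15)
    cfg = SimulationConfig(n_particles=10_000, seed=1234)
    return sweep_master_variable(grid, vary="xi0", config=cfg)


def make_trace(mz: np.ndarray, n_periods: int) -> MagnetizationTrace:
    """Wrap a synthetic periodic signal as a MagnetizationTrace."""
    n = len(mz)
    dt = n_periods / n
    return MagnetizationTrace(
        t_star=np.arange(n) * dt,
        mz_mean=mz,
        mz_sem=np.zeros(n),
        n_particles=1,
        n_periods=n_periods,
        dt_star=dt,
    )
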