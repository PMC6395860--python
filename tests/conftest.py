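"""Shared fixtures.

The heavy session fixtures (calibrated networks, PRC batches) are scoped
to the whole session and shared between the acceptance tests; unit tests
only use the light ones.  Calibrations start from the package's default
drive guesses, so the first request pays the full gradient loop.
"""

import numpy as np
import pytest

from ctcstim import calibrate, netsim, phase, prc
from ctcstim.params import NA

SEED = 20260921


@pytest.fixture(scope="session")
def col075():
    """Calibrated single column at sigma_n = 0.075 nA."""
    cfg = netsim.build_single_column(noise_level=0.075 * NA, seed=1)
    cal = calibrate.calibrate_drives(cfg, seed=SEED)
    assert cal.converged
    return cal


@pytest.fixture(scope="session")
def ctx075(col075):
    return prc.train_phase_model(col075.config, "A", seed=SEED + 1)


@pytest.fixture(scope="session")
def run075(col075):
    """One 10 s run of the calibrated column (shared analysis target)."""
    return netsim.simulate(col075.config, 10.0, seed=SEED + 2)


@pytest.fixture(scope="session")
def prc_batch_075(col075, ctx075):
    """PRC batches: 300 trials at +2 nA, 150 at +4 nA, 300 controls."""
    tau_grid = np.arange(0.0, 0.1001, 0.005)
    trials = prc.run_pulse_experiment(
        col075.config, [2 * NA, 4 * NA],
        {0.0: 300, 2 * NA: 300, 4 * NA: 150},
        seed=SEED + 3, target="A", ctx=ctx075)
    shifts = {amp: prc.pair_and_shift(trials[amp], trials[0.0],
                                      tau_grid=tau_grid)
              for amp in (2 * NA, 4 * NA)}
    return trials, shifts


@pytest.fixture()
def sine_trace():
    fs = 1000.0
    t = np.arange(0, 3.0, 1 / fs)
    return phase.AnalogTrace(np.cos(2 * np.pi * 65 * t), fs)
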