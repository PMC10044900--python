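"""Session fixtures: calibrated pulse configuration and the shared
simulation runs that several test modules interrogate.

The heavy runs are session-scoped so the full Fricke scenarios (20
histories at N = 1; 3 histories at N = 1000, L = 2 um) are computed once.
"""

import dataclasses
import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))   # for the brownian oracle

import frickesim as fs

CAL_SEED = 12345
RUN_SEED = 42
DENSE_SEED = 17
N1_HISTORIES = 20
DENSE_CONCS = {1e-5: 3, 3e-4: 2, 1e-2: 2, 1.0: 3}   # conc -> histories


@pytest.fixture(scope="session")
def reaction_set():
    return fs.load_reaction_set("fricke_cystamine_full")


@pytest.fixture(scope="session")
def calibration(reaction_set):
    """(calibrated PulseConfig, iteration log)."""
    return fs.calibrate_initial_yields(fs.PulseConfig(), reaction_set,
                                       seed=CAL_SEED)


@pytest.fixture(scope="session")
def calibrated_config(calibration):
    return calibration[0]


@pytest.fixture(scope="session")
def baseline_runs(calibrated_config, reaction_set):
    """Calibrated N = 1 runs: aerated/deaerated baselines and the two
    cystamine concentrations of the conventional-dose-rate scan."""
    runs = {}
    for label, aerated, conc in [
        ("aerated", True, 0.0), ("deaerated", False, 0.0),
        ("cys_1e-5", True, 1e-5), ("cys_1", True, 1.0),
    ]:
        medium = fs.standard_fricke_medium(cystamine=conc, aerated=aerated)
        runs[label] = fs.run_pulse_experiment(
            calibrated_config, medium, reaction_set,
            n_histories=N1_HISTORIES, master_seed=RUN_SEED)
    return runs


@pytest.fixture(scope="session")
def dense_runs(calibrated_config, reaction_set):
    """N = 1000 aerated runs at scaled-down conditions (L = 1 um, 2-3
    histories, 4 re-pairing sweeps per decade) across the cystamine ladder.
    The yield is insensitive to L at this sweep cadence."""
    pulse = dataclasses.replace(calibrated_config, n_tracks=1000, length_um=1.0)
    opts = fs.IRTOptions(sweeps_per_decade=4.0)
    runs = {}
    for conc, n_hist in DENSE_CONCS.items():
        medium = fs.standard_fricke_medium(cystamine=conc)
        runs[conc] = fs.run_pulse_experiment(
            pulse, medium, reaction_set, n_histories=n_hist,
            master_seed=DENSE_SEED, options=opts)
    return runs
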