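"""Shared fixtures: all EEG inputs are generated programmatically."""

import numpy as np
import pytest

from mibci import synthdata
from mibci.io_epochs import epoch_trials, pool_phase


def session_epochs(config):
    """Generate a session and pool all its runs into one EpochSet."""
    recordings, markers, truth = synthdata.generate_session(config)
    sets = [
        epoch_trials(r, markers.for_run(r.run_id), cue_time=config.cue_onset)
        for r in recordings
    ]
    return pool_phase(sets), recordings, markers, truth


@pytest.fixture(scope="session")
def strong_session():
    """90-trial phase-1 pool with strong (depth 0.6) contralateral ERD."""
    cfg = synthdata.SimulationConfig(
        n_runs=3, n_phase1_runs=3, erd_depth=0.6, seed=11
    )
    epochs, recordings, markers, truth = session_epochs(cfg)
    return {"config": cfg, "epochs": epochs, "recordings": recordings,
            "markers": markers, "truth": truth}


@pytest.fixture(scope="session")
def null_session():
    """90-trial pool with no class-discriminative content (erd_depth 0)."""
    cfg = synthdata.SimulationConfig(
        n_runs=3, n_phase1_runs=3, erd_depth=0.0, seed=12
    )
    epochs, recordings, markers, truth = session_epochs(cfg)
    return {"config": cfg, "epochs": epochs, "recordings": recordings,
            "markers": markers, "truth": truth}


@pytest.fixture(scope="session")
def tiny_session():
    """One 10-trial run: fast fixture for I/O and plumbing tests."""
    cfg = synthdata.SimulationConfig(
        n_runs=1, n_trials_per_run=10, erd_depth=0.6, seed=5
    )
    epochs, recordings, markers, truth = session_epochs(cfg)
    return {"config": cfg, "epochs": epochs, "recordings": recordings,
            "markers": markers, "truth": truth}


@pytest.fixture(scope="session")
def nf_session_result():
    """One full simulated neurofeedback subject-session (6 runs, ERD 0.6)."""
    from mibci.online import simulate_nf_session

    return simulate_nf_session(subject_seed=42)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
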