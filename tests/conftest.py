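import numpy as np
import pytest

import ovigait as og


@pytest.fixture(scope="session")
def healthy_design():
    return og.GaitDesign()


@pytest.fixture(scope="session")
def healthy_trial(healthy_design):
    """Noiseless walking pass at the healthy-baseline design (6 cycles)."""
    return og.generate_trial(healthy_design, noise=og.ZERO_NOISE, n_cycles=6)


@pytest.fixture(scope="session")
def conditioned_trial(healthy_trial):
    trial, _ = og.preprocess_trial(healthy_trial)
    return trial


@pytest.fixture(scope="session")
def trial_events(conditioned_trial):
    return og.detect_trial_events(conditioned_trial)


@pytest.fixture(scope="session")
def forelimb_cycle(conditioned_trial, trial_events):
    hoof = conditioned_trial.marker("DPHAL_FL_L")
    centre = float(np.mean(
        hoof.positions[:, conditioned_trial.axes.progression])) / 1000.0
    return og.extract_cycle(trial_events["FL_L"], conditioned_trial, "FL_L", centre)


def make_marker(label, positions, occluded=None):
    return og.MarkerTrajectory(label, np.asarray(positions, dtype=float), occluded)


def static_global_trial(n=50, head_dz=100.0, head_dx=30.0):
    """Constructed static trial with just the axial markers (mm units)."""
    t1 = np.tile([0.0, 0.0, 800.0], (n, 1))
    head = t1 + [head_dx, 250.0, head_dz]
    t13 = t1 + [0.0, -250.0, -50.0]
    l7 = t13 + [0.0, -200.0, -30.0]
    return og.Trial(
        animal_id="toy", session="B1", sample_rate=200.0,
        markers={
            "HEAD": make_marker("HEAD", head),
            "T1": make_marker("T1", t1),
            "T13": make_marker("T13", t13),
            "L7": make_marker("L7", l7),
        },
    )
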