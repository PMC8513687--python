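import numpy as np
import pytest

import quadcell as qc


@pytest.fixture(scope="session")
def small_geometry():
    return qc.ArrayGeometry(rows=6, cols=6, pitch_um=58.0)


@pytest.fixture(scope="session")
def baseline_beat():
    """Baseline beat fiducials with jitter removed (noiseless round trips)."""
    return qc.beat_params("BASELINE_0NM", jitter_sd_ms=0.0)


@pytest.fixture(scope="session")
def baseline_ep():
    return qc.ep_params("BASELINE_0NM")


@pytest.fixture
def single_pulse_train():
    return qc.StimTrain(onsets_ms=np.array([0.0]))


@pytest.fixture(scope="session")
def paced_monolayer():
    """Noiseless, gradient-free monolayer for single-pixel pacing tests."""
    params = qc.monolayer_params("BASELINE_0NM", seed=0)
    return params.model_copy(
        update={"beat": params.beat.model_copy(update={"jitter_sd_ms": 0.0})}
    )
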