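import numpy as np
import pytest

from bcivmr import (TaskConfig, PerturbationSchedule, LearningModel,
                    generate_session)
from bcivmr.synthetic_session import make_population


@pytest.fixture(scope="session")
def tiny_session():
    """8-unit, 24-trial session for fast structural tests."""
    from bcivmr import make_fixtures
    return make_fixtures("tiny", seed=0)


@pytest.fixture(scope="session")
def adapted_session():
    """Mid-sized noisy session with adapting noncontrolling populations.

    Fast learning (reaching a stable aim within the rotation block) so that
    late-rotation readouts have a strong ground-truth signal.
    """
    rng = np.random.default_rng(11)
    specs = (make_population(30, "M1", True, rng)
             + make_population(14, "PMd", False, rng)
             + make_population(14, "PRR", False, rng))
    gains = {"controlling": 1.0, "PMd:noncontrolling": 1.0,
             "PRR:noncontrolling": 0.4}
    learning = LearningModel(learning_rate=0.01, retention=0.999,
                             adaptation_gain_by_population=gains, seed=11)
    schedule = PerturbationSchedule(n_baseline=96, n_rotation=160, n_washout=48)
    return generate_session(TaskConfig(), schedule, specs, learning)


@pytest.fixture(scope="session")
def noiseless_session():
    """Deterministic noise-free session with no learning (oracle baseline)."""
    rng = np.random.default_rng(7)
    specs = make_population(30, "M1", True, rng, noise_sd=0.0, latent_rank=0)
    learning = LearningModel(learning_rate=0.0, seed=7)
    schedule = PerturbationSchedule(n_baseline=8, n_rotation=8, n_washout=8)
    return generate_session(TaskConfig(), schedule, specs, learning,
                            round_counts=False)
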