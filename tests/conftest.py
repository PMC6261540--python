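import numpy as np
import pytest
from hypothesis import settings

import voroperim as vp
from voroperim.models import ModelSpec, TrainedModel, build_cnn, fit_arrays

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def pattern_24_2():
    return vp.bundled_pattern("24-2")


@pytest.fixture(scope="session")
def pattern_g1():
    return vp.bundled_pattern("G1")


@pytest.fixture
def toy_pattern():
    """Five locations, one flagged as blind spot."""
    return vp.TestPattern(
        pattern_id="toy5",
        x=np.array([-10.0, 0.0, 10.0, 15.0, -5.0]),
        y=np.array([5.0, 0.0, -5.0, 2.0, -12.0]),
        blind_spot=np.array([False, False, False, True, False]),
    )


@pytest.fixture(scope="session")
def small_cohort(pattern_24_2):
    """A compact labeled cohort for protocol tests (not the full study size)."""
    config = vp.SynthConfig(n_control_subjects=6, n_eg_subjects=6, visits_per_eye=(2, 2), seed=11)
    records, roster = vp.generate_dataset(config)
    return config, records, roster


def _scotoma_images(n: int, rng: np.random.Generator):
    """Linearly separable image family: flat noise vs deep focal scotoma."""
    X = rng.normal(0.0, 1.0, size=(n, 61, 61, 1))
    y = np.zeros(n, dtype=int)
    y[n // 2 :] = 1
    X[n // 2 :, 10:25, 10:25, 0] -= 15.0
    return X, y


@pytest.fixture(scope="session")
def separable_trained_cnn():
    """CNN trained to a perfect ranking on the separable scotoma family."""
    rng = np.random.default_rng(42)
    X, y = _scotoma_images(200, rng)
    perm = rng.permutation(200)
    tr, va = perm[:160], perm[160:]
    spec = ModelSpec(kind="CNN", seed=3, epochs=12)
    net = build_cnn(spec)
    history, best = fit_arrays(net, X[tr], y[tr], X[va], y[va], spec)
    model = TrainedModel(spec=spec, net=net, history=history, selected_epoch=best)
    return model, X, y
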