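import numpy as np
import pytest
from hypothesis import settings

from rlbmi import GeneratorConfig, default_session

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def gen_config() -> GeneratorConfig:
    return GeneratorConfig()


@pytest.fixture(scope="session")
def small_session(gen_config):
    return default_session(gen_config)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def make_separable_session(n_trials=30, n_signals=8, hi=40, lo=0, seed=0):
    """Deterministic, noiseless, perfectly separable two-class session:
    the first half of the signals fire ``hi`` spikes on A trials and
    ``lo`` on B trials; the rest are constant."""
    from rlbmi import TrialRecord
    from rlbmi.synth import _balanced_labels

    labels = _balanced_labels(n_trials, np.random.default_rng(seed))
    half = n_signals // 2
    out = []
    for t, lab in enumerate(labels, start=1):
        counts = np.full(n_signals, 10, dtype=np.int64)
        counts[:half] = hi if lab == "A" else lo
        out.append(TrialRecord(counts=counts, label=lab, index=t))
    return out
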