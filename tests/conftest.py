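import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "deterministic",
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("deterministic")

from imbalmetrics import LabeledScores


@pytest.fixture
def four_instance_data() -> LabeledScores:
    """The hand-countable 4-instance example used across the curve tests."""
    return LabeledScores([1, 0, 1, 0], [4.0, 3.0, 2.0, 1.0])


@pytest.fixture
def random_small_datasets():
    """Deterministic stream of small random labeled-score datasets with ties."""

    def make(n_datasets: int, max_size: int = 50, seed: int = 2024):
        rng = np.random.default_rng(seed)
        out = []
        while len(out) < n_datasets:
            n = int(rng.integers(2, max_size + 1))
            labels = rng.integers(0, 2, size=n)
            if labels.sum() in (0, n):
                continue
            # rounding forces tied scores so the tie conventions are exercised
            scores = np.round(rng.normal(size=n), 1)
            out.append(LabeledScores(labels, scores))
        return out

    return make
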