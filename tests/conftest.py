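import numpy as np
import pytest

from gapcross import (
    SynthConfig,
    generate_cohort,
    generate_trial,
)
from gapcross.posture import build_posture_matrix, embed, fit_pca


@pytest.fixture(scope="session")
def default_config() -> SynthConfig:
    return SynthConfig()

@pytest.fixture(scope="session")
def noiseless_config() -> SynthConfig:
    return SynthConfig().noiseless()


@pytest.fixture(scope="session")
def noiseless_trial(noiseless_config):
    return generate_trial(noiseless_config, "A0", 15.0, seed=1)


@pytest.fixture(scope="session")
def small_cohort(default_config):
    """Default synthetic cohort: 6 animals x 2 trials x 3 distances."""
    return generate_cohort(
        default_config, n_animals=6, trials_per_condition=2, seed=0,
        include_emg=False,
    )


@pytest.fixture(scope="session")
def cohort_embeddings(small_cohort):
    mats = [build_posture_matrix(t) for t in small_cohort.trials]
    model = fit_pca(mats)
    return model, [embed(m, model) for m in mats]


def best_state_accuracy(pred: np.ndarray, truth: np.ndarray, k: int) -> float:
    """Frame-wise accuracy after optimal label matching."""
    from itertools import permutations

    return max(
        float(np.mean(np.asarray(perm)[pred] == truth))
        for perm in permutations(range(k))
    )
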