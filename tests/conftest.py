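import numpy as np
import pytest

from squatstab.pipeline import dataset_from_cohort
from squatstab.synth import SynthConfig


@pytest.fixture(scope="session")
def cohort():
    """A mid-size synthetic cohort run through the full preprocessing chain.

    6 subjects x 40 squats at the default study conditions; shared across
    test modules because generation + featurization is the expensive part.
    """
    cfg = SynthConfig(n_subjects=6, squats_per_subject=40, seed=11)
    dataset, truth, n_detected = dataset_from_cohort(cfg)
    return {"config": cfg, "dataset": dataset, "truth": truth,
            "n_detected": n_detected}


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
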