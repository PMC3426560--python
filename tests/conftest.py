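import numpy as np
import pytest

from antforage import FeedbackParams, SlotSeries, SyntheticTrialSpec, gen_paired_trial


@pytest.fixture
def params():
    """Field-calibrated constants: q=0.05, d=0, floor=0.01 ants/slot."""
    return FeedbackParams(c=0.1)


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)


@pytest.fixture
def small_trial():
    """A short noiseless synthetic trial with known c."""
    spec = SyntheticTrialSpec(
        return_rate=0.8, true_params=FeedbackParams(c=0.08), seed=11
    )
    return gen_paired_trial(spec)


@pytest.fixture
def flat_series():
    return SlotSeries(np.full(200, 2.0))
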