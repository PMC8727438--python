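import numpy as np
import pandas as pd
import pytest

from typeage.simulate import CohortParams, generate_cohort, strong_signal_params


def make_events(timestamps, types=None, subject="s1"):
    """Build a minimal event DataFrame from timestamps (one subject)."""
    ts = np.asarray(timestamps, dtype=float)
    if types is None:
        types = ["alphanumeric"] * len(ts)
    return pd.DataFrame({
        "subject_id": [subject] * len(ts),
        "timestamp": ts,
        "event_type": list(types),
    })


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20210739)


@pytest.fixture(scope="session")
def small_cohort():
    """A compact strong-signal cohort shared by model-level tests."""
    params = strong_signal_params(60, seed=11)
    metadata, events, profiles = generate_cohort(params)
    return {"params": params, "metadata": metadata, "events": events,
            "profiles": profiles}


@pytest.fixture(scope="session")
def small_features(small_cohort):
    from typeage.features import compute_feature_table
    return compute_feature_table(small_cohort["events"], small_cohort["metadata"])
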