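import pytest

from emostate.mapping import load_example_ratings
from emostate.preprocess import location_features, resample_5min, temporal_features
from emostate.labeling import build_labeled_dataset
from emostate.synth import GeneratorConfig, PersonProfile, generate


@pytest.fixture(scope="session")
def rating_table():
    return load_example_ratings()


@pytest.fixture(scope="session")
def small_table():
    """Two synthetic persons, 2 days each, light missingness."""
    profiles = [
        PersonProfile("A", n_days=2, rho=1.0, missing_rate=0.2,
                      report_gap_minutes=(10, 30)),
        PersonProfile("B", n_days=2, rho=0.8, missing_rate=0.4,
                      report_gap_minutes=(10, 30)),
    ]
    return generate(GeneratorConfig(profiles=profiles, seed=42))


@pytest.fixture(scope="session")
def small_windowed(small_table):
    w = resample_5min(small_table)
    w = temporal_features(w)
    return location_features(w)


@pytest.fixture(scope="session")
def small_labeled(small_windowed, small_table, rating_table):
    return build_labeled_dataset(small_windowed, small_table.events, rating_table)
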