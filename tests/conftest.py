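import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "flamscan",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("flamscan")


@pytest.fixture(scope="session")
def corpus():
    """Default synthetic corpus: 6 training + 2 held-out species, seed 7."""
    from flamscan import simulate_corpus

    return simulate_corpus(7)


@pytest.fixture(scope="session")
def trained_model(corpus):
    """Combined model (5-kb bins, threshold 0.075) from the training species."""
    from flamscan import build_labeled_track, train_combined

    train, _ = corpus
    tracks = [build_labeled_track(sp, 5000, 0.075)[0] for sp in train]
    return train_combined(tracks, 5000, 0.075)
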