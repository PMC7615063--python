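import numpy as np
import pytest

from riftbci.decode import extract_features, train_decoder
from riftbci.synthmeg import SensorLayout, SubjectProfile, simulate_training_session


@pytest.fixture(scope="session")
def layout():
    return SensorLayout()


@pytest.fixture(scope="session")
def profile1():
    return SubjectProfile(seed=1)


@pytest.fixture(scope="session")
def training1(profile1):
    """One default-condition training session (80 trials), reused across tests."""
    return simulate_training_session(profile1)


def features_and_labels(rec, labels):
    """Tagging-window feature matrix (n_trials x 14) from a training recording."""
    feats = [
        extract_features(rec.meg()[:, s : s + int(rec.srate)], rec.srate)
        for s, code in rec.events
        if code in (11, 12)
    ]
    return np.array(feats), list(labels)


@pytest.fixture(scope="session")
def decoder1(training1):
    rec, labels = training1
    X, y = features_and_labels(rec, labels)
    return train_decoder(X, y, seed=1)
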