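import numpy as np
import pytest

from macroscape import fixtures as fx
from macroscape import tsne

TRAIN_CONFIG = tsne.TsneConfig(
    perplexity=10.0,
    layer_sizes=(2048, 500, 500, 2000, 2),
    epochs=150,
    batch_size=60,
    learning_rate=1e-3,
    seed=7,
)


@pytest.fixture(scope="session")
def cluster_data():
    """3 clusters x 25 members; planted labels, low within-cluster noise."""
    X, labels = fx.clustered_fingerprints(
        n_clusters=3, per_cluster=25, flip_rate=0.02, seed=11
    )
    return X.astype(np.float64), labels


@pytest.fixture(scope="session")
def split_cluster_data(cluster_data):
    """First 20 per cluster for training, last 5 held out."""
    X, labels = cluster_data
    train_idx = np.concatenate([np.arange(c * 25, c * 25 + 20) for c in range(3)])
    test_idx = np.concatenate([np.arange(c * 25 + 20, (c + 1) * 25) for c in range(3)])
    return X[train_idx], labels[train_idx], X[test_idx], labels[test_idx]


@pytest.fixture(scope="session")
def trained_model(split_cluster_data):
    X_train, _, _, _ = split_cluster_data
    return tsne.train(X_train, TRAIN_CONFIG)
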