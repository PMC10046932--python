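import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow], deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def benchmark_run():
    """Train the standard phantom benchmark once per session: 200 train /
    100 test balanced phantoms (tumor contrast 0.3, noise variance 0.002,
    seed 0), compact recurrent network, 30 epochs."""
    from gliopipe import crnn
    from gliopipe.pipeline import standard_benchmark

    train_items, test_items = standard_benchmark(
        n_train=200, n_test=100, seed=0, size=32,
        tumor_contrast=0.3, noise_variance=0.002)
    x_train = np.stack([it.image for it in train_items])
    y_train = np.array([it.label == "tumor" for it in train_items], dtype=np.int64)
    x_test = np.stack([it.image for it in test_items])
    y_test = np.array([it.label == "tumor" for it in test_items], dtype=np.int64)

    net = crnn.build_network(crnn.NetworkSpec.compact(32), seed=0)
    history = crnn.train(net, x_train, y_train, crnn.TrainConfig(epochs=30))
    probs = net.predict_proba(crnn.adapt_images(x_test, net.spec.in_channels))
    pred = (probs[:, 1] > probs[:, 0]).astype(np.int64)
    return {
        "network": net,
        "history": history,
        "y_test": y_test,
        "pred": pred,
        "test_accuracy": float((pred == y_test).mean()),
    }
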