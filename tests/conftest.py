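import numpy as np
import pytest

from lcmunet.synthetic_data import GenConfig, generate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def tiny_dataset():
    """Six 64x64 lesion samples shared across tests."""
    return generate_dataset(GenConfig(n_samples=6, image_size=(64, 64), seed=7))


@pytest.fixture(scope="session")
def overfit_result():
    """One seed-pinned 200-step overfit run of the full model on 8 synthetic
    128x128 samples, shared by the trainability checks (expensive: minutes)."""
    from lcmunet.pipeline import TrainConfig, evaluate, train
    data = generate_dataset(GenConfig(n_samples=8, image_size=(128, 128), seed=42))
    cfg = TrainConfig(epochs=200, batch_size=8, augment=False, seed=0,
                      variant="lcmunet", val_every=25)
    checkpoint, history = train(cfg, data, val_samples=data)
    final = evaluate(checkpoint, data)
    return {"data": data, "config": cfg, "checkpoint": checkpoint,
            "history": history, "final_metrics": final}
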