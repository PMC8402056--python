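import numpy as np
import pytest

from earcount.metrics import evaluate
from earcount.segmenter import LCFCNCounter
from earcount.synthetic import EarGeometry, FieldSimConfig, simulate_dataset


def recovery_config(seed: int) -> FieldSimConfig:
    """Scene config for the parameter-recovery study: 64×64 quadrats,
    3–12 disjoint ears per image."""
    return FieldSimConfig(
        image_size=(64, 64),
        count_law=("uniform", 3, 12),
        ear_geometry=EarGeometry(length=(7, 13), width=(2.5, 4.5)),
        overlap_fraction=0.0,
        seed=seed,
    )


@pytest.fixture(scope="session")
def recovery_run():
    """Train the tiny counter once on 80 synthetic images; share the result.

    100 epochs of clipped SGD; 20 held-out images for evaluation.
    """
    data = simulate_dataset(recovery_config(11), 100, master_seed=11)
    train, test = data[:80], data[80:]
    est = LCFCNCounter(
        epochs=100, learning_rate=1e-4, max_grad_norm=20.0, seed=0
    ).fit(train)
    pred = est.predict(test)
    truths = np.array([d.count for d in test])
    report = evaluate(pred, truths, image_ids=[d.image_id for d in test])
    return {
        "estimator": est,
        "train": train,
        "test": test,
        "pred": pred,
        "truths": truths,
        "report": report,
    }
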