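import numpy as np
import pytest

from dermseg.synthetic import SynthConfig, generate_samples


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def tiny_samples():
    """Four deterministic 96x128 synthetic image/mask pairs."""
    return generate_samples(SynthConfig(n_samples=4, seed=11, height=96, width=128))


def random_mask_pair(rng, shape=(8, 8), p=0.5):
    pred = (rng.random(shape) < p).astype(np.uint8)
    gt = (rng.random(shape) < p).astype(np.uint8)
    return pred, gt


def brute_force_counts(pred, gt):
    """Independent per-pixel enumeration of the confusion counts."""
    tp = fp = tn = fn = 0
    for p, g in zip(np.asarray(pred).ravel(), np.asarray(gt).ravel()):
        if p == 1 and g == 1:
            tp += 1
        elif p == 1 and g == 0:
            fp += 1
        elif p == 0 and g == 1:
            fn += 1
        else:
            tn += 1
    return tp, fp, tn, fn
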