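import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make tests/oracles.py importable

from fcgrcaps import ClassProfile, FCGREncoder, generate_class
from fcgrcaps.capsnet import CapsNet, tiny_config


def _encode_split(pos_gc, neg_gc, n_train, n_test, seed, resolution=64):
    rng = np.random.default_rng(seed)
    hi = ClassProfile("pos", pos_gc)
    lo = ClassProfile("neg", neg_gc)
    train = (generate_class(n_train, hi, rng, "tr_pos")
             + generate_class(n_train, lo, rng, "tr_neg"))
    test = (generate_class(n_test, hi, rng, "te_pos")
            + generate_class(n_test, lo, rng, "te_neg"))
    enc = FCGREncoder(resolution)
    return (enc.transform(train), np.array([r.label for r in train]),
            enc.transform(test), np.array([r.label for r in test]))


@pytest.fixture(scope="session")
def separable_data():
    """Two-class synthetic set with a strong GC contrast (0.60 vs 0.40),
    300/class train and 100/class test at 200 bp, encoded at N = 64."""
    return _encode_split(0.60, 0.40, 300, 100, seed=7)


@pytest.fixture(scope="session")
def null_data():
    """Negative control: identical GC (0.5 vs 0.5), no motifs — no signal."""
    return _encode_split(0.5, 0.5, 300, 100, seed=7)


@pytest.fixture(scope="module")
def tiny_net():
    """A small random capsule net on 8x8 inputs for unit tests."""
    cfg = tiny_config()
    return CapsNet(cfg, rng=np.random.default_rng(11))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
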