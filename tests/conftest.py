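import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles helper

from lmnet.datagen import SynthSpec, generate_synthetic_dataset, partition


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def synth_dataset(tmp_path_factory):
    """Small 4-class synthetic image set, partitioned 6:2:2 (session-wide)."""
    root = tmp_path_factory.mktemp("synth")
    spec = SynthSpec(num_classes=4, n_per_class=40, image_size=32, seed=11)
    manifest = generate_synthetic_dataset(spec, root)
    return partition(manifest, seed=3), root


def set_all_weights_zero(module):
    """Zero every conv/linear weight and bias; leave BN at identity."""
    from lmnet.nn import BatchNorm2d
    for _, m in module.named_modules():
        if isinstance(m, BatchNorm2d):
            continue
        for v in vars(m).values():
            from lmnet.nn.autograd import Parameter
            if isinstance(v, Parameter):
                v.data[...] = 0.0
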