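import os

# single-threaded BLAS keeps runs bit-reproducible across machines; must be
# set before numpy is first imported
os.environ.setdefault("OPENBLAS_NUM_THREADS", "1")
os.environ.setdefault("OMP_NUM_THREADS", "1")
os.environ.setdefault("MKL_NUM_THREADS", "1")

import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_synthetic_dataset():
    """Default 3-class synthetic task converted to 16x16 spectrograms."""
    import sensornet as sn

    spec = sn.SynthSpec(seed=7)
    return sn.dataset_from_windows(sn.generate(spec), (16, 16))
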