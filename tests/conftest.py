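import numpy as np
import pandas as pd
import pytest

from transplast.io import CountMatrix


@pytest.fixture
def toy_counts() -> CountMatrix:
    """4 genes (one mitochondrial) x 3 units with easy hand-checked sums."""
    values = np.array([
        [5, 0, 2],    # MT-G1
        [5, 1, 0],    # G1
        [0, 3, 0],    # G2
        [0, 0, 4],    # G3
    ])
    meta = pd.DataFrame({"library": ["L1", "L1", "L2"]},
                        index=pd.Index(["c1", "c2", "c3"], name="unit_id"))
    return CountMatrix(values, np.array(["MT-G1", "G1", "G2", "G3"], dtype=object),
                       np.array(["c1", "c2", "c3"], dtype=object), meta)


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20260919)
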