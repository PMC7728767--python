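import numpy as np
import pandas as pd
import pytest

from nfykit import synthetic
from nfykit.expression import ExpressionMatrix


@pytest.fixture
def small_matrix() -> ExpressionMatrix:
    """6 genes x 6 samples with two clearly shifted genes (zero noise)."""
    rng = np.random.default_rng(7)
    base = rng.normal(8, 2, size=6)
    ctrl = np.repeat(base[:, None], 3, axis=1)
    kd = ctrl.copy()
    kd[0] -= 3.0  # planted down
    kd[1] += 3.0  # planted up
    values = pd.DataFrame(
        np.hstack([ctrl, kd]),
        index=[f"g{i}" for i in range(6)],
        columns=[f"c{i}" for i in range(3)] + [f"k{i}" for i in range(3)],
    )
    group = pd.Series(["control"] * 3 + ["knockdown"] * 3, index=values.columns)
    return ExpressionMatrix(values, group, mode="array")


@pytest.fixture
def tss_index():
    return synthetic.gen_tss_index(50, seed=11)
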