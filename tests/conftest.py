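import numpy as np
import pandas as pd
import pytest

from cdscreen.io_formats import CASE, CONTROL, ExpressionStudy


def make_study(values: np.ndarray, n_control: int, n_case: int,
               genes=None) -> ExpressionStudy:
    """Wrap a raw matrix into a labelled two-group study."""
    values = np.asarray(values, dtype=float)
    n_rows, n_samples = values.shape
    assert n_samples == n_control + n_case
    genes = genes if genes is not None else [f"g{i}" for i in range(n_rows)]
    samples = [f"c{i}" for i in range(n_control)] + [f"t{i}" for i in range(n_case)]
    groups = pd.Series([CONTROL] * n_control + [CASE] * n_case, index=samples)
    return ExpressionStudy(
        values=pd.DataFrame(values, index=genes, columns=samples), groups=groups
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_study(rng):
    """10 genes x (4 control + 4 case), first 2 genes shifted up by 3."""
    vals = rng.normal(8.0, 0.5, size=(10, 8))
    vals[:2, 4:] += 3.0
    return make_study(vals, 4, 4)
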